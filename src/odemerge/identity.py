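"""Semantic identity of model elements.

Equality of elements across models is decided from a combination of RDF
resource URIs (MIRIAM annotations), the SBO term, and a structured display
name.  Database URIs alone are often insufficient for signaling models —
two species may share a UniProt entry yet be phosphorylated on different
sites — so names are parsed into a :class:`NameRecord` under a fixed naming
convention:

* base name, then underscore-separated modification tokens consisting of a
  one-letter modification type followed by site (residue letter + position),
  e.g. ``ERK_pT188``;
* complexes as components joined by ``:``, with multiplicities given as a
  ``×n`` suffix (ASCII ``x`` accepted), e.g. ``Shc:Grb2×2``;
* an optional compartment tag after ``@``, e.g. ``ERK_pT188@nucleus``.

Parsing followed by serialization is idempotent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

_MOD_TOKEN = re.compile(r"^([a-z])([A-Z][0-9]+)$")
_COUNT_SUFFIX = re.compile(r"^(.*?)(?:[×x]([0-9]+))$")


@dataclass(frozen=True)
class NameRecord:
    """Structured decomposition of a display name."""

    base_name: str = ""
    modifications: frozenset = frozenset()  # of (site, modification-type)
    complex_components: tuple = ()  # sorted ((component-string, count), ...)
    compartment_tag: str = ""

    @property
    def is_complex(self) -> bool:
        return bool(self.complex_components)

    def serialize(self) -> str:
        if self.is_complex:
            parts = []
            for comp, count in self.complex_components:
                parts.append(comp if count == 1 else f"{comp}×{count}")
            core = ":".join(parts)
        else:
            mods = sorted(self.modifications, key=lambda m: (m[0], m[1]))
            core = "_".join([self.base_name] + [f"{t}{s}" for s, t in mods])
        if self.compartment_tag:
            core += f"@{self.compartment_tag}"
        return core

    def compatible_with(self, other: "NameRecord") -> bool:
        """Compatibility when database URIs already pin the molecule: the
        base names may differ (ERK vs. ERK2) but modification state,
        complex composition and compartment tag must agree."""
        return (
            self.modifications == other.modifications
            and self.complex_components == other.complex_components
            and self.compartment_tag == other.compartment_tag
        )


def parse_name(name: str) -> NameRecord:
    """Parse a display name under the naming convention."""
    name = name.strip()
    tag = ""
    if "@" in name:
        name, tag = name.rsplit("@", 1)
        tag = tag.strip()
    components = [c.strip() for c in name.split(":") if c.strip()]
    if len(components) > 1 or (components and _COUNT_SUFFIX.match(components[0])):
        counted = {}
        for comp in components:
            m = _COUNT_SUFFIX.match(comp)
            if m:
                comp, n = m.group(1), int(m.group(2))
            else:
                n = 1
            canon = _canonical_component(comp)
            counted[canon] = counted.get(canon, 0) + n
        return NameRecord(
            base_name=name,
            complex_components=tuple(sorted(counted.items())),
            compartment_tag=tag,
        )
    base, mods = _split_modifications(components[0] if components else "")
    return NameRecord(base_name=base, modifications=frozenset(mods), compartment_tag=tag)


def _split_modifications(text: str):
    tokens = text.split("_")
    base_tokens, mods = [], []
    for tok in tokens:
        m = _MOD_TOKEN.match(tok)
        if m and base_tokens:
            mods.append((m.group(2), m.group(1)))  # (site, type)
        else:
            base_tokens.append(tok)
    return "_".join(base_tokens), mods


def _canonical_component(comp: str) -> str:
    base, mods = _split_modifications(comp)
    mods = sorted(mods, key=lambda m: (m[0], m[1]))
    return "_".join([base] + [f"{t}{s}" for s, t in mods])


@dataclass(frozen=True)
class ElementIdentity:
    """Semantic fingerprint of a model element.

    Equality of two identities is deterministic, symmetric and reflexive.
    """

    rdf_uris: frozenset = frozenset()  # of (qualifier, uri)
    sbo_term: object = None
    structured_name: NameRecord = field(default_factory=NameRecord)

    def semantically_equal(self, other: "ElementIdentity") -> bool:
        """The matching relation used by automatic overlap detection.

        When both sides carry URIs, the URI sets must be equal and the
        structured names compatible (modifications/complex/compartment
        agree; base names may differ).  When either side lacks URIs, full
        structured-name equality is the sole criterion.  SBO terms, when
        present on both sides, must not contradict.
        """
        if (
            self.sbo_term is not None
            and other.sbo_term is not None
            and self.sbo_term != other.sbo_term
        ):
            return False
        if self.rdf_uris and other.rdf_uris:
            return self.rdf_uris == other.rdf_uris and self.structured_name.compatible_with(
                other.structured_name
            )
        return self.structured_name == other.structured_name


def extract_identity(element) -> ElementIdentity:
    """Build the :class:`ElementIdentity` of a loaded element.

    Pure and deterministic: repeated calls on the same element agree.
    Elements without annotations yield an identity carrying only the
    structured name (parsed from the display name, falling back to the id).
    """
    uris = frozenset(tuple(pair) for pair in getattr(element, "cv_uris", ()))
    name = getattr(element, "name", "") or element.id
    return ElementIdentity(
        rdf_uris=uris,
        sbo_term=getattr(element, "sbo_term", None),
        structured_name=parse_name(name),
    )
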
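# Case-study input data

The structural/behavioral case study integrates two curated signaling
models from the BioModels Database:

- `BIOMD0000000262.xml` — EGF-dependent Akt pathway
- `BIOMD0000000263.xml` — NGF-dependent Akt pathway

These third-party files are **not** redistributed with this repository and
cannot be fetched in an offline environment.  To enable the case-study
acceptance tests and the full acceptance report, download the two curated
SBML files from the BioModels Database and place them in this directory
under exactly the names above.

Without them, the case-study tests are skipped and the download-free
property suite is the acceptance surface; `scripts/acceptance.py` then
writes an empty report and says so on stderr.
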
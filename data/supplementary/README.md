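# Supplementary similarity tables (user-supplied)

The reproduction tests in `tests/test_acceptance.py` and the pipeline's
`matrices` mode consume the published Thioalkalivibrio pairwise tables,
which are distributed by the journal as supplementary spreadsheets and are
not bundled with this repository. To run those checks, export each table to
CSV (strain labels in the first row and first column, numeric body) into
this directory:

| file                  | content                          | kind          |
|-----------------------|----------------------------------|---------------|
| `s6_dddh.csv`         | pairwise dDDH values (%)         | dDDH          |
| `s5_anib.csv`         | pairwise ANI_b values (%)        | ANIb          |
| `s5_anim.csv`         | pairwise ANI_m values (%)        | ANIm          |
| `s5_tetra.csv`        | pairwise TETRA correlations      | TETRA         |
| `s4_mlsa_identity.csv`| pairwise MLSA identities (%)     | MLSA-identity |
| `metadata.csv`        | strain metadata                  | —             |

`metadata.csv` needs the columns `strain_id,is_type,species_name,region`
with `is_type` true for the ten described type strains (AL2, ALM2, ALJ12,
ARh2, HL17, ALEN2, ARh1, ALJD, ARhD1, HL-EbGr7) and strain labels matching
the matrices exactly.

Directional ANI pairs are symmetrized by arithmetic mean on load; values in
percent with the diagonal forced to 100 (TETRA: 1.0).
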
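# Data fixtures

This directory holds transcriptions of published Swedish breast-milk CSTD
and dietary-intake tables for BDE-47 (S1), DDT (S2), PCB-153 (S3) and HCB
(S4).  None are currently shipped: the source tables live in a journal
supplement that is not redistributed with this package, and
`cstdkit.synthetic_data.load_fixture` raises a `FixtureNotFoundError`
naming the file to provide.

To add one, transcribe the table into:

- `S<k>_<chem>_cstd.csv` with columns `year, age, conc_ng_per_g_lipid, n`
  (concentration in ng/g milk lipid; `n` optional), and
- `S<k>_<chem>_intake.csv` with columns `year, intake_ng_per_kg_bw_per_day`,

and note the transcription provenance (source table, access date) here.
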
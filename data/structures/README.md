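# Structure files

Place deposited PDB entries here (e.g. `4YAY.pdb`, `6DO1.pdb`) to enable the
crystal-structure worked examples in `tests/test_acceptance.py` and
`scripts/acceptance.py`. They can be fetched once with:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json --allow-download
```

or downloaded manually from https://files.rcsb.org/download/<ID>.pdb.
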
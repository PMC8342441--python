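# conformpath

Analysis toolkit for receptor conformational-pathway studies, built around the
inactive → intermediate → active transition of a class A GPCR in a 2-D
order-parameter space (a Cα–Cα distance in Å and a three-point Cα angle in
degrees):

- **`structure_io`** — PDB reading/writing with altloc resolution,
  Ballesteros–Weinstein (BW) position tables (a curated table for the human
  AT1 receptor is packaged), and Kabsch superposition.
- **`featurize`** — activation order parameters (distance between Cα 5.55 and
  7.46; angle at Cα 6.47 between arms to 6.34 and 2.41) and sin/cos-expanded
  backbone φ/ψ dihedrals.
- **`synthetic_data`** — a three-basin potential surface emulating the
  activation landscape, an overdamped Langevin sampler (Leimkuhler–Matthews
  or Euler–Maruyama), a Boltzmann grid-integration population oracle, and an
  operational-model dose-response generator.
- **`neb`** — nudged-elastic-band minimum-energy paths: energy-dependent
  four-case tangents, perpendicular/parallel force decomposition, a
  simulated-annealing optimizer, and adjacent-distance replica sub-selection.
- **`landscape`** — 2-D free-energy landscapes (`F = -kT ln p/p_max`),
  projection of external structures, and split-based convergence checks.
- **`msm`** — k-means microstates, sliding-window transition counting,
  nonreversible/reversible transition-matrix estimation on the largest
  strongly connected component, implied timescales, PCCA+ coarse-graining,
  a Chapman–Kolmogorov test with honest error bars, and similarity-score
  (`S_ij = exp(-d_ij / d_scale)`) representative-conformation selection.
- **`tpt`** — committors, mean first passage times, and net reactive fluxes.
- **`tica`** — time-lagged independent component analysis via the symmetrized
  generalized eigenproblem.
- **`pharm`** — operational-model (transducer-ratio) dose-response fitting,
  `Δlog(τ/K_A)` relative activities with SEM propagation in quadrature, and
  the mutant × pathway bias heat map.
- **`pipeline`/`cli`** — end-to-end orchestration with plain CSV/JSON
  artifacts and a deterministic summary.

## Tests

```bash
python -m pytest -q tests/
```

The two `test_acceptance.py` crystal-structure checks need the deposited PDB
entries; place `4YAY.pdb` and `6DO1.pdb` under `data/structures/` (or set
`$CONFORMPATH_PDB_DIR`) to enable them. Without network access and without
those files they fail with a `FileNotFoundError` — this is expected offline.

## CLI

```bash
conformpath simulate --out traj.csv --seed 1 --n-steps 100000
conformpath landscape --features traj.csv --bins 100 --out landscape.csv
conformpath msm --features traj.csv --k 200 --lag 300 --macrostates 3 --out msm.json
conformpath tica --features traj.csv --lag 300 --out proj.csv
conformpath neb --start "21.3,38.0" --end "17.4,69.4" --replicas 20 --out band.csv
conformpath featurize --pdb structure.pdb --out features.csv
conformpath pharm --data dose_response.csv --out fits.json
conformpath run --config config.yaml --seed 1 --out run_dir
```

`conformpath run` executes simulate → landscape → MSM (+ implied timescales,
PCCA+, CK) → TPT MFPTs → tICA → report, writing `summary.json` with the
macrostate populations, the MFPT table, and representative frame indices.

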
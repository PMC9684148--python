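# chitopa

Simulation and fingerprint analysis of chitosan acetylation patterns.

Chitosans are binary copolymers of GlcNAc (`A`, acetylated) and GlcN
(`D`, deacetylated) characterised by degree of polymerisation (DP),
fraction of acetylation (F_A), and pattern of acetylation (PA).
`chitopa` provides a desk-scale, fully seeded in-silico pipeline around
these three parameters:

* **`polymer_core`** — chain/ensemble containers and the core statistics:
  F_A, dyad fractions, the deviation-from-randomness statistic
  P_sigma (= P_AD + P_DA; 1 for random, < 1 block-wise, -> 2 alternating),
  run-length ("block") profiles, DP moments/dispersity, and closed-form
  Bernoulli (random-pattern) reference theory.
* **`pattern_synthesis`** — seeded generators: Schulz–Zimm chain-length
  sampling matched to (DPn, Đ), Bernoulli / first-order-Markov /
  deterministic-regular acetylation patterns parameterised by
  (F_A, P_sigma).
* **`cda_kinetics`** — Gillespie kinetic Monte Carlo of reverse-mode
  chitin-deacetylase N-acetylation of polyglucosamine with per-subsite
  preference weights ({-2}, {-1}, {+1} around the modified residue);
  presets `uniform`, `AnCDA`, `PesCDA`, `CnCDA4`, `PgtCDA`.
* **`digestion`** — iterative endo-hydrolysis to the limit digest under
  subsite rules (scissile bond between subsites {-1} and {+1}, residue
  constraints plus occupancy windows); presets `chitinosanase` (the
  DA/XX rule), `ChiB`, `ChT`, `Csn174`, `lysozyme`.
* **`fingerprint`** — enzymatic-MS fingerprint analysis of product
  tables: DP 2–10 normalisation, monomer-weighted F_A estimation,
  block-profile inference from DA/XX products (exact against the
  run-length oracle), block-size averages, profile comparison, and a
  multiplicative-noise layer for semi-quantitative MS abundances.
* **`dyad_nmr`** — simulated dyad peak intensities and the
  P_sigma/F_A estimator from an intensity quadruple.
* **`cli_io`** — FASTA ({A, D} alphabet) and product-CSV round-trip I/O,
  enzyme config files (YAML), and the seeded end-to-end pipeline.

## CLI

```sh
# generate a random-PA ensemble and digest it with the DA/XX rule
chitopa generate --family bernoulli --fa 0.34 --dpn 700 --dispersity 1.8 \
    --n-chains 100 --seed 1 --out chains.fasta
chitopa digest chains.fasta --enzyme chitinosanase --seed 2 --out products.csv
chitopa fingerprint products.csv

# in-silico enzymatic N-acetylation of polyglucosamine
chitopa generate --family bernoulli --fa 0 --dpn 500 --n-chains 50 \
    --seed 3 --out polyglcn.fasta
chitopa acetylate polyglcn.fasta --enzyme PesCDA --target-fa 0.33 \
    --seed 4 --out blockpa.fasta --trajectory traj.csv

# dyad statistics from sequences or four peak areas
chitopa dyads blockpa.fasta
chitopa dyads 0.2637 0.0663 0.0663 0.6037

# closed-form random-pattern expectations
chitopa theory --fa 0.1 --block-size 7 --dp 1000

# full pipeline (generate -> digest -> fingerprint -> dyads -> summary)
chitopa pipeline --seed 5 --out run_dir
```

Enzyme presets live in `src/chitopa/data/*.yaml`; a custom enzyme can be
passed as a YAML file path wherever a preset name is accepted.

## Conventions

* Sequences are written non-reducing end -> reducing end, left to right.
* Residues are 1-based in reports; bond `j` joins residues `j` and `j+1`
  and is indexed by its {-1} residue.
* Monomer mass is treated as 1: dispersity is that of the DP
  distribution.
* Pseudo-time in the kinetic Monte Carlo is dimensionless (k = 1).
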
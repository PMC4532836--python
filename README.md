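# cuproforce

Single-molecule force-spectroscopy analysis of cupredoxin unfolding.

Blue-copper proteins such as azurin and plastocyanin carry two terminal
mechanical clamps of nearly equal strength. Pulled in an AFM, a single
molecule stochastically unfolds from either the N or the C terminus and is
transiently arrested at its Cu centre, so the position of the resulting
mechanical intermediate fingerprints the unfolding direction — a kinetic
partitioning between parallel pathways. `cuproforce` provides the complete
computational side of such an experiment:

* **Polymer mechanics** — Marko–Siggia worm-like chain:
  F(x) = (kT/p)[1/(4(1−x/Lc)²) − 1/4 + x/Lc], forward, inverse, and
  fixed-p contour-length fitting of rising edges.
* **Trace simulation** — kinetic Monte-Carlo pulling of (protein–I27)₄
  polyproteins with Bell–Evans kinetics k(F) = k0·e^{FΔx/kT}, competing
  N/C clamps, Cu-anchored intermediates, holo/apo mixtures; constant
  velocity sawtooths and force-clamp staircases, with ground-truth event
  logs.
* **Trace analysis** — rupture detection (matched step estimator with
  matching-pursuit deconvolution), WLC fitting, I27 fingerprint filtering,
  intermediate pairing and pathway classification, force-clamp step
  detection.
* **Structure calculus** — expected contour-length increments
  ΔL = 0.38·n_released + S_crosslink + d(anchor, far term.) − d(N, C)
  from PDB models, accounting for disulfide-trapped loops, plus metal-site
  coordination geometry.
* **Partition statistics** — exact Hartigan dip statistic with
  simulation-based p-values, pathway fractions with Wilson intervals,
  per-mode "mean ± sd, n" summaries.

Synthetic azurin-like and plastocyanin-like reference structures are
bundled (`cuproforce.refstructs`; coordinates are synthetic stand-ins that
encode the published residue numbering, C3–C26 crosslink and Cu–ligand
bond lengths — see `docs/methods.md`).

## Worked example

Simulate 25 wild-type azurin polyprotein pulls, analyse them, and compare
with the structure-derived predictions:

```sh
cuproforce simulate -n 25 --construct wt-azurin --seed 7 -o traces
cuproforce analyze traces/*.tsv --construct wt-azurin --seed 7 -o analysis
```

```
Construct: wt-azurin
Traces: 25 analyzed, 0 rejected (fingerprint filter), 0 unreadable
Pathway partition:
   two-state:  61.0% (n=61, 95% CI 51.2-70.0%)
     C-first:   9.0% (n=9, 95% CI 4.8-16.2%)
     N-first:  27.0% (n=27, 95% CI 19.3-36.4%)
  four-state:   3.0% (n=3, 95% CI 1.0-8.5%)
Intermediate positions:
  C-terminal: dL = 6.3 +/- 0.3 nm, n=12
  N-terminal: dL = 9.4 +/- 0.5 nm, n=30
Hartigan dip test (vs uniform, 2000 null draws): D = 0.0961, P = 0.0005 (100.0% certainty), n = 42
```

Each analysed azurin module is labelled by the contour-length position of
its Cu-anchored intermediate: ~6 nm means unfolding started at the C
terminus (arrest at the Cu–S(Cys112) bond), ~9 nm at the N terminus
(Cu–N(His46), shortened by the C3–C26 disulfide loop). The bimodal position
sample rejects unimodality with >99.9 % certainty. Two-state events are
over-counted relative to the generating 20 % apo fraction because cascades
faster than the detector's resolution hide their intermediates — a real
instrumental effect the simulator reproduces (see `docs/methods.md`).

The structural side of the same story:

```sh
python -c "from cuproforce.refstructs import write_reference_pdbs; write_reference_pdbs('refs')"
cuproforce predict refs/azurin_synthetic.pdb
```

```
refs/azurin_synthetic.pdb chain A: 128 residues
  disulfide 3-26 (S-S 2.05 A)
  CU-ND1(HIS-46): 1.95 A
  CU-SG(CYS-112): 2.10 A
  ...
terminus  anchor      SS released  dL (nm)
       N    full  intact      104    38.98
       N    full    none      128    47.64
       N      46  intact       21    10.34
       N      46    none       45    19.00
       C     112  intact       16     7.00
```

Full unfolding releases ~39 nm with the disulfide intact and ~48 nm
without it (the loop traps 24 residues ≈ 10 nm); unfolding from the N
terminus to the His-46 Cu anchor releases ~10 nm (19 nm without the
disulfide), and from the C terminus to Cys-112 ~7 nm — the contour
bookkeeping behind the observed ~6 / ~9 nm intermediates.

The same works as a library:

```python
from cuproforce import (default_polyprotein, InstrumentConfig,
                        simulate_constant_velocity, detect_ruptures,
                        fit_events)

trace, truth = simulate_constant_velocity(
    default_polyprotein("wt-azurin"), InstrumentConfig(rng_seed=1))
table = fit_events(trace, detect_ruptures(trace))
```

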
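# slimbind

Quantitative analysis of IxI/V short-linear-motif (SLiM) binding.

Small heat-shock proteins such as HSP27 regulate their oligomeric
assembly through a short [V/I]x[V/I] motif in a disordered C-terminal
region that docks into a groove on the α-crystallin domain (ACD).
Point mutations at the motif's central residue (e.g. a Pro→Leu
substitution) weaken this interaction and shift the oligomer
equilibrium.  `slimbind` implements the quantitative machinery needed
to characterise such an interaction end to end:

* **Titration thermodynamics** (`slimbind.binding`) — weighted amide
  chemical-shift perturbations `dd = sqrt(dH² + (0.2 dN)²)`, a global
  two-state Kd fit of fast-exchange residues through the exact
  mass-balance bound fraction

  `pB = (Kd + Lt + Pt − sqrt((Kd + Lt + Pt)² − 4 Lt Pt)) / (2 Pt)`,

  bound-fraction predictions, and ΔΔG = RT·ln(Kd ratio).
* **CPMG relaxation-dispersion kinetics** (`slimbind.cpmg`) — exact
  two-site Bloch–McConnell propagation of the echo train
  (`R2,eff(ν) = −ln(I/I0)/T`), a closed-form oracle, global multi-field
  fits in *naive* (ΔR2 = 0) and *constrained* (fixed pB, free ΔR2)
  modes, and conversion to kinetics: `koff = (1−pB)·kex`,
  `kon = pB·kex/Lfree`, `Kd = koff/kon`.
* **Proteome motif census** (`slimbind.census`) — [V/I]x[V/I] counts in
  whole proteomes, disordered regions (≥20-residue intervals) and the
  structured remainder, expectations from amino-acid-frequency
  independence (`N = M·Πq p(AAq)`), and the total χ² enrichment test on
  ν = 76 degrees of freedom.
* **Peptide conformational analysis** (`slimbind.traj`) — backbone φ/ψ
  dihedrals, Ramachandran free-energy surfaces
  (`ΔG = −kB·T·ln(n/n_max)`), Kabsch superposition and
  combined-ensemble Cα PCA.
* **Synthetic data** (`slimbind.synth`) — seeded generators for every
  input class (titrations, dispersions, proteomes with disorder masks
  and planted motifs, dihedral-sampled peptide trajectories) with
  machine-readable ground truth, so the whole pipeline is testable
  without external data.

## Worked example

Binding kinetics from synthetic two-field ¹⁵N dispersion data planted
with a wild-type-like exchange state (`examples/cpmg_rates.py`):

```text
planted: pB = 2.40%  koff = 515 /s
fitted : pB = 2.42 +/- 0.03%  kex = 515 +/- 13 /s  (reduced chi2 0.81)
rates  : koff = 502 +/- 13 /s  kon = 2.85e+05 /M/s  Kd(CPMG) = 1760 uM
```

The fit recovers the planted bound-state population (2.4%) and
off-rate within uncertainty; the derived Kd (~1.8 mM) is an order of
magnitude weaker than the titration Kd (~125 µM) under the same
two-state assumptions — the same discrepancy that, on real data,
signals a third (bound-state) process and motivates the constrained
fixed-pB/free-ΔR2 analysis mode.

The other examples are equally short narrative scripts:

* `examples/titration_kd.py` — global Kd from a 16-residue titration
  (planted 124 µM, fitted 120 ± 2 µM) and the ~5 kJ/mol ΔΔG of a
  125 µM → 1 mM affinity loss;
* `examples/motif_census.py` — census of a proteome with 40 planted
  disordered IPV motifs (χ²_tot = 1096 at ν = 76 in disordered
  regions vs 73 in structured ones; Pro centre enriched by +36
  percentage points);
* `examples/ramachandran_pca.py` — a proline-like motif centre
  occupies 23/1296 Ramachandran bins against 347/1296 for a
  leucine-like centre, and widens the PCA cloud of the whole peptide
  (0.3 → 16.1 Å²).

A thin CLI mirrors the library (`slimbind titrate-fit | cpmg-fit |
slim-census | traj-analyze | simulate | pipeline`); run any subcommand
with `--help`.

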
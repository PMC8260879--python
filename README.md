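# oligomerkit

Quantitative analysis of membrane-receptor oligomerization: how many
receptor molecules associate (dimers? trimers?), how stable the oligomers
are, and how the answer shows up in three independent kinds of data —
spectrally-resolved FRET, fluorescence-intensity-fluctuation (FIF)
molecular brightness, and molecular-dynamics trajectories.

It is written for quantitative cell biologists and biophysicists who
measure receptor association in the plasma membrane (e.g. receptor
tyrosine kinases such as the Eph receptors) and need the model-fitting
machinery behind those measurements as tested, scriptable code.

## The models

**Mass-action equilibrium.** n monomers M associate into an n-mer with a
two-dimensional dissociation constant K_diss = [M]ⁿ/[Mₙ] in
(receptors/μm²)^(n−1). At total surface density R_total the free monomer
density solves

    [M] + n·[M]ⁿ/K_diss = R_total

and the oligomeric fraction is f = (R_total − [M])/R_total. The apparent
dissociation constant of an n-mer is the density at which f = 1/2
(R_half = 2(K/n)^(1/(n−1)); for n = 2, R_half = K_diss). Dimer stability is
ΔG = RT·ln(K_diss/10⁶) kcal/mol against the 1 receptor/nm² standard state.

**FRET forward model.** Each membrane region reports donor density,
acceptor density, and an apparent FRET efficiency. A donor inside an
n-mer has k acceptor partners with probability Binom(k; n−1, x_A) and
transfers with per-donor efficiency kẼ/(kẼ + 1 − Ẽ), where Ẽ is the
intrinsic (pairwise) FRET — a structural parameter. Predicted FRET is
f·Ē(n, x_A, Ẽ), which for dimers reduces to the familiar f_D·x_A·Ẽ.
Nonspecific proximity FRET from 2-D crowding is removed with a
Wolber–Hudson-type correction before fitting. Fitting minimizes the mean
squared error over (K_diss, Ẽ); comparing minimized MSE across n = 1..6
selects the oligomer order.

**FIF molecular brightness.** Images are tiled into 15×15-pixel segments;
each segment's brightness ε = σ²/⟨I⟩ − 1 (photon counting) converges to
λ·⟨s²⟩/⟨s⟩, the particle-weighted oligomer size times the monomer
brightness λ — so dimers read 2λ and trimers 3λ. Histogram modes over
thousands of segments, optionally restricted to high receptor densities
where monomers are scarce, reveal the dominant oligomer size.

**Trajectory networks.** Per-residue RMSF against a reference structure
(averaged over replicates), Shrake–Rupley SASA (probe 1.4 Å), and a
dynamical network over α-carbons: edges join non-consecutive residues
within 4.5 Å for ≥75% of frames, weighted by motion correlation
C_ij (path weight −log|C_ij|), partitioned into communities of
coordinated residues by the Girvan–Newman algorithm.

A synthetic-data module generates FRET tables, FIF image stacks, and toy
trajectories with exactly the statistical structure these estimators
assume, so every stage is testable end to end without external data.

## Worked example

Fit a synthetic dimer dataset (K_diss = 1050 receptors/μm², Ẽ = 0.55,
300 regions, FRET noise sd 0.03) and select the oligomer order:

```python
from oligomerkit import FretTruth, generate_fret_dataset, select_order, free_energy

dataset = generate_fret_dataset(FretTruth(seed=1))
sel = select_order(dataset)            # fits n = 1..6
best = sel.fits[sel.best_order]
print(sel.best_order)                  # 2
print(round(best.k_diss), round(best.e_tilde, 3))   # 968 0.542
print(round(free_energy(best.k_diss), 2))           # -4.11
```

The MSE minimum falls at n = 2 (the generating order), the fitted
dissociation constant lands within ~8% of the planted 1050 receptors/μm²,
and the implied dimerization free energy is −4.11 kcal/mol. The same
pipeline run on trimer-forming truth (half-saturation 580 receptors/μm²)
returns n = 3 with a fitted half-saturation of 569 receptors/μm² (see
`analysis/02_fret_order_selection.py`).

The `analysis/` directory holds numbered narrative drivers for each stage
(equilibrium energetics, FRET order selection, FIF brightness histograms,
trajectory networks); each writes its tables under `results/`. The same
functionality is exposed on the command line:

```bash
oligomerkit simulate fret --seed 1 --out sim/
oligomerkit fit-fret --input sim/fret.csv --orders 1-6 --out fit.json
oligomerkit deltaG --kdiss 1050        # -4.0638
oligomerkit fif --images manifest.csv --mode photon --min-conc 3000 --out fif/
oligomerkit traj communities --reference ref.pdb --replicate r1.pdb --out comm.csv
```

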
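# foldstab

Quantitative analysis of protein fold stability from three orthogonal
biophysical readouts, built for studies that ask whether a covalent
modification (e.g. attachment of ubiquitin or another bulky modifier)
destabilizes the fold of a substrate protein:

* **Tryptophan-fluorescence melts** — emission spectra F(λ) collected across
  temperature or denaturant concentration are condensed to the barycentric
  mean wavelength ⟨λ⟩ = Σλ·F(λ) / ΣF(λ), and the resulting melting curve is
  fitted to the Boltzmann sigmoid

  λ(T) = λ_N + (λ_D − λ_N) / (1 + exp((T½ − T)/rate)),

  giving the transition midpoint T½ per replicate. Replicates are summarized
  as mean ± SEM and constructs compared by a two-tailed pooled Student's
  *t* test.
* **Differential scanning calorimetry** — baseline-corrected Cp(T) traces are
  analyzed by peak-maximum transition temperature (valid for irreversible
  transitions where equilibrium thermodynamic fits are not), and folding
  reversibility is quantified per transition as the reheat/first-heat peak
  area ratio.
* **¹⁵N backbone relaxation** — per-residue T1/T2 decays are fitted
  mono-exponentially with Monte Carlo errors, the heteronuclear NOE is
  averaged over duplicate experiments, and (R1, R2, NOE) are converted by
  reduced spectral density mapping to J(0), J(ω_N), J(0.87ω_H) with
  first-order error propagation. J(0) is sensitive to slow (µs–ms) motions,
  so the per-residue J(0) ratio between modified and unmodified forms is a
  destabilization profile; an isotropic rotational correlation time is
  estimated from the trimmed R2/R1 ratio.

A synthetic-data generator (`foldstab.synthgen`) emulates all three
experiment types — two-state melting spectra with red-shifting emission,
van't Hoff DSC endotherms with partial reversibility, and Lipari–Szabo
model-free relaxation data — so every stage of the pipeline is testable and
calibratable end to end without instrument data.

## Worked example

Simulate a free and a mono-ubiquitylated construct (ground-truth midpoints
332.1 K and 316.5 K, 3 replicates each at 2% intensity noise), fit them, and
compare:

```
$ foldstab --seed 3 simulate melt --out fk --midpoint 332.1
$ foldstab --seed 4 simulate melt --out ub --midpoint 316.5
$ foldstab fit-melt fk_melt.tsv --out fk_fits.tsv
midpoint = 332.10 +/- 0.00 (SEM, n=3)
$ foldstab fit-melt ub_melt.tsv --out ub_fits.tsv
midpoint = 316.51 +/- 0.01 (SEM, n=3)
$ foldstab compare-melt fk_fits.tsv ub_fits.tsv
delta = -15.60  t = -1581.761  p = 9.58e-13
```

The fitted group means recover the generating midpoints to within their SEM,
the midpoint shift of −15.6 K quantifies the destabilization, and the
pooled t test shows the shift is far beyond replicate noise. The same
library calls are available in Python (`simulate_melt_series`,
`build_melt_curve`, `fit_sigmoid`, `aggregate_replicates`,
`compare_transitions`).

A two-component DSC trace (a destabilized substrate transition plus a
modifier transition 20 K higher) with reversibility analysis:

```
$ foldstab --seed 5 simulate dsc --out d --tm 325.5 --tm 345.5
$ foldstab dsc-analyze d_first_heat.tsv --reheat d_reheat.tsv --out dsc.tsv
peak: T_m = 325.5 K, height = 70.43
peak: T_m = 345.5 K, height = 61.98
```

Relaxation analysis from simulated decay/NOE tables to spectral densities:

```
$ foldstab --seed 6 simulate relax --out rx --n-residues 8 --tau-m 6
$ foldstab fit-relax --t1 rx_t1.tsv --t2 rx_t2.tsv --noe rx_noe.tsv --out recs.tsv
fitted 8 residues -> recs.tsv
$ foldstab jmap recs.tsv --out dens.tsv
mapped 8 residues; isotropic tau_c = 5.27 ns
$ foldstab jratio dens.tsv dens.tsv --out ratio.tsv --attributes attr.txt
J(0) ratio = 1.00 +/- 0.00 (8 residues)
```

`attr.txt` is a plain two-column per-residue attribute file for coloring a
structure in common molecular viewers.

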
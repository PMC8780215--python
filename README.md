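# cmapscan

Analysis toolkit for **CMAP scan** examinations: simulation of motor-unit
pools and the descending-intensity scan protocol, the **D50** discontinuity
index, model-based **motor unit number estimation** (MUNE) in the style of
MScanFit, and the two-group cohort statistics used in clinical CMAP-scan
studies.  It is aimed at clinical neurophysiologists and methods researchers
who want a tested, reproducible reference implementation of the full
pipeline — from stimulus–response curve to group p-values — without access
to proprietary EMG hardware software.

A CMAP scan delivers ~500 electrical stimuli to a motor nerve with intensity
declining linearly across the recruitment range and records the compound
muscle action potential (CMAP) amplitude evoked by each.  Motor unit *j*
fires all-or-none with probability Φ((I − μ_j)/(rs_j·μ_j)) at intensity *I*
(mA); the amplitude is Σ a_j over firing units plus baseline noise.  From
the curve the package computes:

* **max CMAP** (mV, baseline to negative peak);
* **D50**: with amplitudes ranked as % of max, A₁ ≤ … ≤ A_N, consecutive
  differences ΔA_n = A_{n+1} − A_n re-ranked largest first and accumulated
  into M, D50 is the smallest n with M_n > 50% — few, large (reinnervated)
  units give a small D50;
* **MUNE**: a motor-unit-pool model is fitted to the scan by stochastic
  local search against a windowed rank + scatter discrepancy; the procedure
  runs three times and the minimum-error run is accepted when its
  percentage error is < 7%.

The 13-subject tetraplegia table from the study this pipeline reproduces is
packaged as a fixture (`table1_sci_cohort.tsv`), so the cohort stage's
headline numbers are exactly recomputable.  See `docs/methods.md` for the
model, every numerical choice, and known limitations.

## Worked example

Simulate an SCI-like muscle with exactly 59 motor units, then analyse it:

```
$ cmapscan simulate --group sci --n-units 59 --seed 1 --out scan.csv
wrote scan.csv: 59 units, max CMAP 11.34 mV, range 7.6-20.6 mA

$ cmapscan d50 scan.csv
D50: 63
max CMAP (mV): 11.3359
N: 500

$ cmapscan mune scan.csv --seed 1
MUNE: 45
percentage error: 1.041%
per-run errors: 1.046%, 1.041%, 1.195%
```

The simulated muscle truly has 59 units; the model-based estimate recovers
45 from the scan alone (unit counts are identified only up to the scan's
noise resolution, so estimates run somewhat low), with the best of three
fitting runs matching the recorded curve to 1.0% of the maximum CMAP —
comfortably under the 7% acceptance rule.  D50 = 63 says this particular
curve is smooth; discontinuous curves from strongly reinnervated muscles
give much smaller values.

Cohort statistics on the packaged per-subject table:

```
$ cmapscan cohort
...
mune                 59.3846 ± 36.7594
cmap_mV              8.01308 ± 3.97311
d50                  37.2308 ± 17.4793
...
```

i.e. MUNE 59 ± 37, CMAP 8.01 ± 3.97 mV and D50 37 ± 17 for the SCI group,
with the MUNE-vs-injury-duration Pearson correlation r = −0.51 (p = 0.08).
`cmapscan all --seed 1` chains simulate → d50 → mune → cohort into a run
directory with a checksum manifest.

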
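# nucoff

Kinetic models of transcription-factor (TF) dissociation from nucleosomal
DNA, for quantitative chromatin biophysics: given only a TF's naked-DNA
off-rate and equilibrium constants, how much faster should it dissociate
when its binding site sits in the entry–exit region of a nucleosome?

Single-molecule FRET experiments report accelerations of two to three
orders of magnitude.  `nucoff` implements the two passive mechanisms that
could produce this and lets you compute which one can:

* **Dimeric binding** — a homodimeric TF (e.g. LexA) releases one
  half-site at a time; the nucleosome rewraps onto the released half-site
  and blocks rebinding, ratcheting the TF off.  This mechanism reaches a
  50–200-fold acceleration.
* **Non-specific binding** — the TF slides base by base off its specific
  site onto surrounding DNA while the nucleosome rewraps behind it.  This
  mechanism saturates below one order of magnitude: a negative result.

## Model

Every kinetic scheme is a master equation dX/dt = R·X on labeled states;
the detected "off" state (TF free, nucleosome fully wrapped) is made
absorbing by zeroing its outgoing rate, and the measured off-rate is the
magnitude of the slowest nonzero eigenvalue of R.  For the 4-state
naked-DNA dimer model this eigenvalue has the closed form

    k_off = ½[(k₁ + 2k₂ + k₃) − √((k₁ + 2k₂ + k₃)² − 8k₂k₃)]

with k₁ half-site rebinding, k₂ half-site release from the dimer, k₃ last
half-site release.  Together with k₁/k₂ = 1000 (half-site affinity
penalty), k₂ = k₃, and K_d = 0.07 nM, the measured k_off = 0.0034 s⁻¹
determines all rates.  Nucleosome wrapping enters through a free-energy
landscape ΔG(n) (kBT per n bp unwrapped): single-bp rewrap at
k₀ = 10⁵ s⁻¹, unwrap at k₀e^(−ΔΔG-step), coarse-grained into the rates
k₅–k₈ of the 7-state nucleosome model.  A Gillespie stochastic simulation
provides an independent check of every eigenvalue.

## Worked example

```python
import nucoff as nc

params = nc.fit_naked_dimeric(target_off=0.0034, ratio=1000.0, kd_full=0.07)
print(params.k1, params.k2, params.k4_per_conc)
# 1705.0966101615077 1.7050966101615077 0.02435852300230725

scan = nc.ddg_scan(params)   # ddG = 5..7 kBT, conc = 0
print(scan)
#    ddg_kBT  off_rate_s  fold_change
# 0     5.00    0.195057    57.369618
# 4     6.00    0.384704   113.148148
# 8     7.00    0.631938   185.864159
```

The fitted rates say a LexA dimer rebinds a released half-site ~1000×
faster than it lets go of the last one — which is why naked-DNA
dissociation is slow.  The scan couples those rates to nucleosome
rewrapping at unwrapping penalties ΔΔG = 5–7 kBT and shows the off-rate
rising to 0.20–0.63 s⁻¹: a 57–186-fold acceleration purely from the
nucleosome capturing transiently released half-sites.

The sliding model, by contrast, fitted the same way and maximized over its
unknowns (specificity ratio K, sliding rate k₁, steric clearance d,
concentration), never exceeds a 10-fold change:

```python
lmb = nc.synthetic_landscape(147, 35.0)          # 35-kBT linear landscape
df = nc.scan_nonspecific(lmb)                    # 35 (K, k1) conditions
print(df.fold_change.max())                      # < 10
```

Each `examples/*.py` script is a short narrative of one capability
(fitting, the ΔΔG scan, mutant and entry–exit predictions, the sliding
scan, landscapes, the Gillespie cross-check); run them with `python`.
A thin CLI mirrors the library: `nucoff dimeric fit`, `nucoff dimeric
scan`, `nucoff nonspecific scan --out scan.tsv`, `nucoff landscape synth`,
`nucoff simulate`, `nucoff run --config cfg.yaml`.

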
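# camfret

Quantitation of calmodulin-binding domains from ratiometric FRET biosensor
titrations.

A practical route to locating unknown calmodulin (CaM)-binding sequences in a
G protein-coupled receptor is to sandwich each candidate submembrane fragment
between a donor/acceptor fluorescent-protein pair and titrate purified
Ca²⁺-CaM while monitoring emission: specific binding disrupts FRET, raising
donor emission (475 nm) and lowering acceptor emission (535 nm). `camfret`
implements the full analysis for that workflow — for biophysicists running
cuvette titrations on a spectrofluorometer, and for anyone who wants to
stress-test the analysis on realistic synthetic data.

## The models

**Fractional response.** With R = F475/F535 and R_min/R_max the ratios in the
unbound and maximally bound states,

    BS_fract = (R − R_min) / (R_max − R_min),

with single-channel analogues for the dilution-corrected donor and acceptor
intensities. The dynamic range DR = R_max/R_min proxies the binding-induced
conformational change.

**Apparent K_d.** Bound fraction versus titrated CaM is fit to the hyperbola
f = [CaM]/(K_d + [CaM]) or, when the biosensor concentration [BS] is not
negligible against K_d (ligand depletion), to the exact mass-action root

    f = ((K_d+[BS]+[CaM]) − √((K_d+[BS]+[CaM])² − 4·[BS]·[CaM])) / (2·[BS]).

Fits run in measured-ratio space with R_min, R_max and K_d jointly free, with
multi-start seeding across a 10⁻²–10³ µM K_d grid.

**Ca²⁺ sensitivity.** Free Ca²⁺ is read from a co-monitored indicator
(X-Rhod5F-like, K_d 1.6 µM): [Ca²⁺] = 1.6·(F−F_min)/(F_max−F). Biosensor
fraction versus free Ca²⁺ is fit to the Hill equation
BS_fract = [Ca²⁺]ⁿ/(EC₅₀ⁿ + [Ca²⁺]ⁿ); biphasic curves are decomposed by a
segmented fit (species 1 below 1 µM free Ca²⁺ with free amplitude, the global
fit standing for the dominant species 2), with an F-ratio test deciding
whether the segmentation is warranted.

**Synthetic data.** `simulate_cam_titration` and `simulate_ca_assay` emulate
the experiments end to end — dilution schedules, depletion binding,
chelator/CaM-buffered free Ca²⁺ via a mass-balance solver, the indicator
channel, Gaussian-peak emission spectra, and seeded multiplicative channel
noise — so every estimator can be validated by parameter recovery.

## Worked example

```python
import camfret as cf

# a noiseless titration of a high-affinity linker: Kd 0.44 µM, DR 1.61,
# 0.5 µM biosensor — then fit it back
cfg = cf.GeneratorConfig(true_kd=0.44, r_min=1.0, r_max=1.61, seed=7)
series = cf.simulate_cam_titration(cfg)
response = cf.apply_dilution_correction(series)
fit = cf.fit_binding(response, bs_total=0.5, model="auto")
print(fit.summary())
```

```
Biosensor-CaM binding fit
=========================================
isotherm model     : quadratic
response model     : affine_ratio
n points           : 31
apparent Kd (uM)   : 0.44 +/- 6.81e-16
R_min / R_max      : 1.0000 / 1.6100
dynamic range      : 1.61
RSS                : 3.06916e-30
converged          : True
note: auto-selected quadratic model (Kd 0.44 µM < 10 × [BS] 0.5 µM)
```

The fit auto-selects the depletion (quadratic) isotherm because the recovered
K_d (0.44 µM) is comparable to the 0.5 µM biosensor concentration, and
recovers the generating K_d, endpoint ratios and dynamic range exactly. The
same round-trip through a simulated Ca²⁺ assay
(`simulate_ca_assay` → `run_ca_assay`) recovers EC₅₀(Ca²⁺) and the Hill
coefficient, and flags two-species mixtures as biphasic.

A `camfret` console script exposes the same pipeline from the shell:
`camfret simulate`, `camfret fit-kd`, `camfret fit-ca`, `camfret design`
(see `camfret --help`).

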
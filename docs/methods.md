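# Methods

## Severity calculus

Three severity ordinates are implemented.

* `SF = log10(t · exp((T − T_ref)/14.75))`, with `t` in minutes and
  `T_ref` = 100 °C by default — the classical hydrothermal severity factor.
* `CSF = SF − pH`. The acidity credit is subtracted *outside* the
  logarithm (the Chum convention). A typographic variant that subtracts pH
  inside the log bracket circulates in the literature; it is dimensionally
  incoherent and is not supported.
* `CSF_ext = (T − T_ref)/ω + ln t + m·ln C_sol + n·ln C_cat`, natural
  logarithms, `t` in minutes, concentrations in mol/L. For formic-acid
  (FA) fractionation the acid is both solvent and catalyst, so the
  catalyst term is absorbed into the solvent order (`n = 0`) and
  `T_ref` = 70 °C, the bottom of the 80–107 °C operating window. Note the
  deliberate base change: SF/CSF are base-10 by tradition; `CSF_ext` uses
  natural logs, which is what reproduces the packaged reference table.

**wt% → mol/L.** Lab sheets give FA strength in weight percent while the
severity formula wants molarity, so `C = 1000·ρ·w / 46.03` with a pinned
density table ρ = {60%: 1.131, 70%: 1.153, 80%: 1.174, 90%: 1.192} g/mL.
These values coincide with standard ambient-temperature densities of
aqueous formic acid and were cross-checked by back-solving `ln C_FA` from
the 32 severity entries of the packaged reference campaign under the
pooled-variant constants. The table is exact-key (no interpolation) and
user-overridable; temperature dependence of density is out of scope.

**Constant presets.** Two conventions ship per family. The defaults,
`arrhenius-table1` (ω = 14.54, m = 12.10) and `logistic-table1`
(ω = 13.91, m = 12.52), are the pooled xylan-plus-lignin fits and
reproduce the reference severity table to within ±0.02 on 31 of 32
entries. The source report also prints a second pair of constants
(`arrhenius-eq7`: 16.795/12.165, `logistic-eq8`: 16.32/12.67) that is
mutually inconsistent with its own severity table; both are exposed, the
table-consistent pair is the default. Two provenance corrections are
baked in and worth knowing about:

* the pooled and total-biomass parameter rows of the source table are
  printed with the (slope, m, ω) columns permuted against its own header;
  the package stores the corrected ordering, the only reading under which
  the severity table reproduces;
* run 12's Arrhenius severity is printed as 32.28 but evaluates to ≈43.50
  under every constant set tried; it is treated as a transcription error
  and excluded from reproduction checks (its Logistic entry, 44.90, is
  consistent).

## Solubilization curves

Both families map the linear predictor `η = slope·CSF_ext + intercept` to
α ∈ (0, 1): cloglog (`α = 1 − exp(−exp η)`, first-order removal kinetics)
and logistic (`α = expit(η)`, removal rate proportional to both removed
and remaining fraction). Evaluation saturates the predictor at ±700 and
uses `expm1`/`expit`, so extreme severities degrade gracefully to 0/1
without overflow. In float64 the cloglog curve reaches exactly 1 once
`exp(η) ≳ 36`; round-trip identities in transformed space are therefore
only meaningful below that, while the α-space round trip holds to 1e−10
across (1e−4, 1 − 1e−4).

**Clipping.** Observed α at or outside [ε, 1 − ε], ε = 1e−4, is clipped to
the band with a warning naming the records (a drop policy is available).
Clipping rather than dropping keeps full factorial campaigns usable when a
component is completely removed at the harshest corner.

## Joint fitting

The linearized model `y = β0 + β1(T − T_ref) + β2 ln C + β3 ln t` is fit
by OLS (statsmodels); `ω = β3/β1`, `m = β2/β3`, slope `= β3`, intercept
`= β0`. Degenerate designs (any factor at a single level, or collinear
predictors) raise an identifiability error rather than being silently
regularized; `|β1|` or `|β3|` below 1e−10 raises an extraction error, as
does a negative estimated ω (possible under heavy noise, where the
campaign simply fails to identify the temperature scale).

Diagnostics: R², F (k = 3 model degrees of freedom) and the F-test
p-value are computed on the transformed scale the regression runs on —
the natural choice for a model fit *as* a linear regression — with an
α-scale R² reported alongside for transparency. Shifting `T_ref` by Δ
changes only the intercept (by `slope·Δ/ω`) and none of ω, m, slope or R².

Four data-processing variants are supported — xylan, lignin, pooled
xylan-plus-lignin (derived through the mass balance, treating the pair as
one pseudo-soluble fraction), and total biomass (1 − solid yield) — with a
comparison report ranked by R², the criterion under which the pooled
variant is generally preferred.

A direct nonlinear least-squares fit of untransformed α over
(ω, m, slope, intercept) (`scipy.optimize.least_squares`, LM) serves as an
independent cross-check; on noiseless data the two routes agree to 1e−6
per parameter. Under noise they differ by construction (different error
scales) and no equality is asserted.

## Mass balance

`α = 1 − SY·content/initial_fraction` per component, with feedstock
defaults for depithed sugarcane bagasse (43.4% glucan, 24.4% xylan,
24.2% Klason lignin, plus minor fractions). The lignin basis defaults to
Klason-only and the xylan basis to xylan-only (arabinan excluded):
Klason-only tracks the reference campaign's printed delignification within
~1–3 pp, while no basis reproduces the printed xylan-removal column
exactly (discrepancies up to ~9 pp on one run; the basis used there is
unrecorded). Derived values are therefore never asserted equal to printed
removal columns — only proximity diagnostics are used. Out-of-range α from
measurement noise is clamped to [0, 1], warning when the excursion exceeds
0.02. Composition sums slightly above 1 (independent assays over-closing
the balance) are tolerated up to 1.05 with a warning. Enzymatic glucan
conversion uses the standard anhydro correction
`EGC = 0.9·glucose/glucan` (162/180).

## Synthetic data

The generator emulates a factorial fractionation campaign: default grids
T ∈ {80, 90, 99, 105} °C, FA ∈ {60, 70, 80, 90} wt%, t ∈ {0.25, 0.5, 1,
1.5} h; parameter-recovery studies extend the time grid to 2 h for an
80-point campaign. Noise is Gaussian on the transformed scale (matching
the OLS error model); σ defaults to 0.15, which puts the realized R² of
the pooled fit near the reference fits' 0.83–0.92 on these designs. An
α-scale additive-noise mode exists for robustness experiments. Ground
truths default to the reference fits per component; glucan — whose real
behavior is weakly non-monotone in severity — is simplified to a low-slope
monotone curve (slope 0.03, intercept −2.8, giving α ≈ 0.15–0.25 over the
design range), chosen so composition tables remain realistic. Composition
records are built by inverting the mass balance (`SY = 1 − Σ α_c·c0`,
unmodeled components assumed retained), so the forward balance recovers
each α exactly.

What passing tests show — and don't: the generator reproduces the
*statistical structure* the fitting assumes (factorial design, additive
transformed-scale noise, exact curve family). Real campaigns add
model-misspecification, per-assay error structure, replicate correlation
and the non-monotone glucan response, none of which are emulated; recovery
precision measured here is an upper bound on what real data would give.

A variant generator tunes the noise amplitude of a single draw so the
fitted R² equals a requested target exactly (scaling one standard-normal
noise vector; the scale is found by root-finding). It backs the
diagnostics self-consistency check: an 80-point campaign at R² = 0.8337
necessarily yields F ≈ 127 (F is a deterministic function of R², k and n),
so the computed F falling in (100, 160) checks internal consistency, not
agreement with any particular dataset.

On recovery precision at these study conditions: with σ = 0.15 on the
80-point design, the OLS sampling distribution (which is also the
Cramér–Rao bound for this generative model) gives median relative errors
of roughly 16% for ω, 10% for m, 9% for the slope and 4% for the
intercept. ω is intrinsically the hardest: it is a ratio of two
coefficients, one of which (β1) is small. Tighter recovery requires either
lower noise (σ ≈ 0.075 halves the errors) or a wider design.

## Pipeline & I/O

Files carry percent and hours (as lab sheets do); the in-memory model uses
fractions and minutes, converted only at the I/O boundary. Configs and fit
outputs are JSON, tables CSV. The pipeline (simulate → invert mass
balance → derive variants → fit both families → severity reproduction
report) records seed, preset, density-table hash, clipping ε and bases in
a provenance block, and is byte-identical under a fixed seed. The 16-run
reference campaign and the lime-deformylation results ship as packaged
CSVs; the deformylation data are stored as data only (no deformylation
chemistry is modeled).

## Known limitations

* Phenomenological only: no mechanistic delignification kinetics,
  component interactions, or time-resolved integration.
* Exact-key density table; no temperature correction.
* Glucan's non-monotone solubilization and the formylation/EGC responses
  are not modeled (EGC is handled only as a derived measurement).
* Curve-deviation reporting is in absolute percentage points of α.
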
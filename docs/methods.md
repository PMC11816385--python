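# Methods

## The model

`bwsle` describes the solid–liquid equilibrium (SLE) of a binary mixture of
two compounds A and B that are fully miscible as liquids and immiscible as
solids. Each compound defines a liquidus *branch*: the temperature at which
its pure solid coexists with the liquid mixture at composition `x` (the
molar fraction of the branch compound in the liquid). The measured melting
temperature of the mixture at any composition is the *higher* of the two
branch temperatures — the pointwise branch maximum is the liquidus, and the
branch crossing is the eutectic point.

For an ideal solution, melting-point depression is purely entropic and the
branch obeys

    1/T = 1/Tm − R ln(x) / ΔHm,

with `Tm` the pure-compound melting temperature, `ΔHm` its enthalpy of
fusion, and `R = 8.31446 J/(mol·K)`. The Bragg–Williams (regular-solution)
correction models non-ideal mixing through a single parameter `zw`: the
number of nearest-neighbour contacts per molecule, `z`, times the energy
change `w = E_AB − E_AA/2 − E_BB/2` of replacing like contacts by an unlike
contact. Random (composition-proportional) mixing of contacts adds a
partial molar mixing enthalpy `(1 − x)² zw` to the liquid-phase chemical
potential, which closes to the explicit branch temperature

    T = [1 + (zw/ΔHm)(1 − x)²] / [1/Tm − (R/ΔHm) ln(x)].

`zw = 0` recovers the ideal branch exactly; `zw < 0` (mixture contacts more
favourable than pure-liquid contacts) depresses the liquidus and deepens
the eutectic — the deep-eutectic-solvent regime; `zw > 0` raises it. The
same assumptions throughout: equal contact numbers for both species,
enthalpy ≈ internal energy, solid-phase immiscibility, and negligible
heat-capacity change on melting (no Δcp correction is offered).

When `zw` is negative enough that the bracketed numerator goes
non-positive, the branch has no physical solution at that composition.
Such values are represented by NaN — never a negative kelvin — and a
branch that is nonphysical somewhere simply cannot be the liquidus there.
Only if *both* branches are nonphysical at some composition is the model
rejected (`NonphysicalModelError`).

## Estimating zw

**Grid fit** (`BraggWilliamsSLE`, `fit_zw_grid`). Candidates scan −100 to
+100 kJ/mol in 0.1 kJ/mol steps; for each candidate the liquidus (branch
maximum) is evaluated *directly at the experimental compositions* — never
interpolated from a display grid — and the objective is the average
absolute deviation (AAD, kelvin) over the interior data points. The
reported fit minimises the AAD; because zw = 0 is on the grid, the fitted
model can never be worse than the ideal curve. Exact ties break toward the
smallest |zw| (parsimony toward the ideal model), and between ±|zw| toward
the negative value, making the argmin deterministic. An optional bounded
continuous refinement within one grid step (`refine=True`) is off by
default so the plain protocol is the discrete grid.

**Per-point inversion** (`PointwiseZw`, `estimate_zw_from_point`). The
branch equation is algebraically invertible at a single melting point:

    zw = [ΔHm (T/Tm − 1) − R T ln(x)] / (1 − x)².

Each point yields two candidate estimates, one per branch; the numerically
smaller is kept — the larger would imply, for the other compound, a
melting temperature above the one actually measured. Point estimates are
combined by an inverse-variance weighted mean,
`mean = Σ(zw_i/σ_i²)/Σ(1/σ_i²)`, with standard error `1/√(Σ 1/σ_i²)` (the
usual uncertainty of an inverse-variance weighted mean; the choice of this
formula is ours — no alternative is canonical here).

**Error propagation.** First-order propagation of the inversion gives, for
an uncertainty ΔT in the measured temperature, Δ(ΔHm) in the enthalpy of
fusion, and ΔTm in the pure melting temperature:

    Δzw = [ΔHm/Tm − R ln(x)] / (1−x)² · ΔT
    Δzw = |T/Tm − 1| / (1−x)² · Δ(ΔHm)
    Δzw = ΔHm·T/Tm² / (1−x)² · ΔTm

These are exact partial derivatives of the inversion formula (the tests
verify them against central finite differences at 1e−4 relative
tolerance). All three diverge as (1−x)⁻² at the pure-compound boundaries:
a melting point at x = 0.999 carries ~2.5·10⁵ times the zw uncertainty of
one at x = 0.5. Errors are evaluated at the point's *measured* temperature
on the *chosen* branch, and defaults mirror common uncertainty
assumptions: 5 K on T, 5 kJ/mol on ΔHm, 5 K on Tm. The forward direction
is benign: the liquidus responds to a zw perturbation as
`ΔT = (1−x)²/ΔHm · T_ideal(x) · Δzw`, bounded for all compositions — so
fitting all points is well-conditioned even though single-point inversion
near the boundaries is not.

## Numerical choices

- Internal units are strictly J/mol and kelvin; files and user-facing
  surfaces use kJ/mol (conversion only at the I/O and CLI boundary).
- Composition grids for curve output use `n` equally spaced *interior*
  points `x_i = i/(n+1)` (default n = 1000); the endpoints are handled
  analytically (`T(x→1) = Tm` exactly, independent of zw) since the log
  term is singular at x = 0.
- Compositions within 1e−6 of 0 or 1 are excluded from estimation with a
  warning; they are singular for the (1−x)⁻² inversion.
- The eutectic is located as the grid minimum of the liquidus, refined by
  bisection on the branch difference `T_A(x) − T_B(x)` to a default
  temperature tolerance of 1e−6 K (the difference is continuous and
  monotone near the crossing for the simple diagrams in scope). If the
  branches never cross inside (0, 1), the boundary-adjacent grid minimum
  is returned with `branch_crossing=False`.
- Dataset CSVs round-trip bit-exactly (shortest-repr floats on write,
  correctly rounded parsing on read).

## The synthetic generator

`generate_dataset` emulates what an SLE experiment measures: `n` points at
compositions in a sub-interval of (0, 1) (default [0.05, 0.95], uniform
grid or uniform random), temperatures on the *liquidus* of a known model —
the branch maximum, not a single named branch, so the estimator's branch
selection is genuinely exercised — plus additive Gaussian noise on
temperature only (compositions are prepared gravimetrically and treated as
exact). The default noise of 1 K reflects typical melting-point scatter;
it is deliberately distinct from the 5 K / 5 kJ/mol uncertainty
*assumptions* used for error bars. Per-replicate seeds in
`recovery_experiment` derive deterministically from the master seed via
`numpy.random.SeedSequence`, so every experiment replays exactly.

What passing the synthetic tests does **not** show: the generator has no
DSC peak broadening, supercooling, metastability, polymorphism, solid
solubility or composition error, so recovery results bound performance
only under the model's own assumptions, not on real mixtures with complex
phase behaviour.

## Known limitations

- **Branch misselection near the boundaries.** Under temperature noise, a
  point near x = 1 can have its (correct) branch estimate scattered by
  hundreds of kJ/mol; when noise pushes it above the *other* branch's
  estimate, the min-rule selects the wrong branch, whose value is
  meaningless yet carries a deceptively small propagated error — and the
  weighted mean follows it. This is intrinsic to the per-point procedure;
  the practical guidance (reflected in our recovery experiments) is to
  place estimation points well inside the composition range, e.g.
  x ∈ [0.2, 0.8], where the weighted mean is unbiased and its ±1 SE
  interval covers the truth at roughly the nominal 68% rate. The grid fit
  over all points does not suffer from this.
- The model assumes equal contact numbers for both species, so it is
  nominally restricted to similar-sized molecules; it represents *all*
  deviations from ideality — enthalpic and entropic — in one parameter.
- Only simple eutectic diagrams are in scope: no polymorphism, solid
  solutions, peritectics, ternary mixtures, or unequal contact numbers.
- The grid fit's resolution is its step (0.1 kJ/mol by default); on
  noise-free data the fitted zw is within one step of truth, never better,
  unless `refine=True`.
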
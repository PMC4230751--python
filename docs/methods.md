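# Methods

## Model and assumptions

The neuron is a passive ball-and-stick model: an iso-potential spherical
soma of diameter `D` (membrane area `pi D^2`) attached at `z = 0`, with
zero coupling resistance, to a uniform cylindrical dendrite of diameter `d`
and length `l` whose distal end is sealed. Soma and stick share the
specific membrane resistance `R_m` (Ohm m^2), capacitance `C_m` (F/m^2)
and axial resistivity `R_i` (Ohm m); the membrane is strictly linear (RC),
so every frequency can be treated independently and output PSDs are input
PSDs times transfer functions. Quasi-active (linearized conductance)
membranes, conductance-based noise, branched or tapered morphologies, and
near-field LFP forward modelling are out of scope.

Dimensionless coordinates: `W = 2 pi f tau` with `tau = R_m C_m`;
`X = x/lambda`, `L = l/lambda` with `lambda = sqrt(d R_m / (4 R_i))`;
`q = sqrt(1 + iW)` on the principal branch (`Re q >= 1`, enforced so all
hyperbolic identities hold); `b = pi D^2 G_m / G_inf` with
`G_inf = pi d^(3/2) / (2 sqrt(R_m R_i))` the semi-infinite-stick DC
conductance; `B = b q` because soma and stick share membrane properties.

## Single-input solution

Solving `V'' = q^2 V` with the lumped-soma boundary `V'(0) = B q V(0)` and
a sealed distal end gives, for a unit current at `X'`, the three transfer
functions listed in the README, all over the common denominator
`D = sinh(qL) + B cosh(qL)`. The dipole closed form follows from
integrating the z-weighted membrane return current by parts; the boundary
terms collapse to `H_p = lambda (V(0) - V(L))` per unit input current — an
identity the test suite re-derives numerically by Gauss-Legendre
quadrature of the return-current profile.

Sign conventions: outward membrane current positive, z-axis toward the
distal end, and the injected current counts as an inward transmembrane
current at its injection site. Consequently the signed currents sum to
zero (the dipole moment is translation invariant), a somatic injection is
part of the measured net soma current (its transfer differs from a
proximal-stick injection by exactly the injected current, while the soma
potentials coincide), and homogeneous fully correlated input makes the
neuron iso-potential with exactly zero net soma current and dipole moment.

## Distributed input

Sources of identical PSD `s(f)`, densities `n_d`/`n_s` and pairwise
coherence `c(f)` combine as
`S = s [ (1-c)(T_us + T_ud) + c T_c ]`, with `T_ud` a position integral of
`|H|^2` over the stick and `T_c` the squared modulus of the area-weighted
sum of transfers. The six stick integrals of hyperbolic products are
solved in closed form and validated against adaptive quadrature to 1e-9
relative; a Riemann-sum evaluator over single-input transfers provides an
independent discrete route. The relative input density is defined as
`rho = n_s/(n_s + n_d)` (0.5 for the default equal densities, 0 for
dendrite-only input); it is isolated in one function,
`relative_input_density`, and validated by the `rho -> 0` continuity of
the correlated soma-potential component and by Riemann sums for mixed
soma/dendrite correlated input.

## Numerical evaluation

Hyperbolic functions overflow double precision beyond `|q|L ~ 700`, and
the slope analysis probes `W` up to `1e8` (`|q|L ~ 7000`). All transfer
functions and integrals are therefore evaluated in exponentially scaled
form: numerators and denominators are multiplied by `exp(-Re(q) L)` (or
its square) so that every exponential has a non-positive real-part
argument. At `W = 0` the `sin(2 beta L)/beta`-type terms are replaced by
their analytic limits. Degenerate inputs are rejected with named-parameter
messages (non-positive physical parameters, positions outside the stick,
coherence outside [0, 1], `f = 0` for pink/Brownian input, soma-potential
queries on a neuron with `b = 0` and somatic input).

## Asymptotics

For `W >> 1`, dropping exponentially decaying terms gives
`T ~ A W^(-alpha_inf)` with half-integer `alpha_inf` stored as exact
`Fraction`s and amplitudes hard-coded in terms of the biophysical
parameters (e.g. `A = n_d pi d lambda / sqrt(2)` for the
uncorrelated-dendrite soma current). The expansions are not re-derived
symbolically at runtime; they are validated numerically: a log-log fit
over `W` in `[1e6, 1e8]` must recover each exponent to 0.01 and each
amplitude to 0.5% (the amplitude is compared at the top of the window,
since extrapolating the fit intercept to `W = 1` inflates the residual
slope error; soma-class amplitudes carry `O(1/(b sqrt(W)))` corrections
that are ~2% at `W = 1e5`). The correlated soma-potential case has two
branches: exponent 2 for any non-zero somatic density and 3 for
dendrite-only input. With all input types present, the smallest exponent
of the contributing classes wins — `1/2`, `3/2` and `2` for soma current,
dipole and soma potential: for the potential the uncorrelated somatic
`W^-2` term dominates the dendritic `W^-5/2` term, which is also why the
mixed-noise slope tends to `3 = 2 + 1` under pink input.

## Slopes and regimes

The local slope `mu(f) = -d log S / d log f` is evaluated by symmetric
finite differences in log-log space: half-width 1/120 decade on the
analytic transfer (accurate to ~1e-6 for these smooth curves), and a
1/60-decade central-difference stencil (`np.gradient`) for tabulated PSDs.
Regime boundaries are the lowest crossings of `mu` through configurable
fractions (default 0.10 and 0.90) of `alpha_inf`; all crossings are also
reported because soma-input soma-potential curves on compact sticks are
non-monotone. Slope maps realize each `(b, L)` pair through a synthetic
physical parameter set (`params_from_dimensionless`), so the exact closed
forms are reused unchanged; maps converge in `L` — beyond roughly
`L = 8` doubling the stick changes no slope by more than 0.01.

## Input-noise models and synthesis

White, pink (`s0 f_ref/f`) and Brownian (`s0 (f_ref/f)^2`) spectra use a
reference frequency `f_ref = 1 Hz` and hold the spectrum flat below a
low-frequency cutoff `f_cut = 0.1 Hz` to bound synthesized power; the
synapse models are the Lorentzian `s0/(1 + (2 pi f tau_s)^2)`
(exponential synapse, high-frequency slope 2) and its square (alpha
synapse, slope 4), default `tau_s = 1 ms`. Time series are synthesized as
sums of sinusoids, one per FFT frequency, with amplitudes
`sqrt(2 s(f) df)` and seeded uniform random phases, assembled by inverse
real FFT; the Nyquist and DC bins are zeroed. A fixed seed reproduces the
series bit for bit, Welch periodograms match the model per octave within
20%, and band-integrated power agrees with the sample variance within 5%.

## Mixed-noise scenario

A high-conductance variant of the default neuron (`R_m` reduced tenfold to
0.3 Ohm m^2, mimicking an in-vivo state) receives two uncorrelated,
homogeneously distributed input populations: pink noise (putative
ion-channel noise) and synaptic noise. Each component is scaled
analytically — by integrating its soma-potential PSD over 0.2–100 Hz —
so the pink component's standard deviation is 0.6 mV and the total 2.5 mV;
no time-domain simulation enters the targeting. The crossover is the
lowest frequency above 1 Hz where the component PSDs intersect
(log-linear interpolation), reported as absent when they never cross.
The synaptic time constants are package defaults (1 ms for both synapse
models); the crossover location depends strongly on them, so only the
structural facts (variance targets, crossover existence, slope limits of
3/4/6 for pink/exponential/alpha input) are treated as test anchors.

## Compartmental oracle

The independent validator discretizes the neuron into a lumped soma plus
`n` uniform dendritic segments, potentials at segment centers, axial
resistances between centers (half a segment between the soma and the first
center), and solves the complex tridiagonal admittance system per
frequency with a banded LU factorization — no hyperbolic-function code is
shared with the closed forms. Kirchhoff holds to machine precision by
construction; convergence to the analytic solution is second order in the
segment length, and 800 segments keep all modalities within 0.5% over
0.1 Hz–10 kHz. Distributed-input PSDs weight each segment by
`density x area` and sum `|F|^2` (uncorrelated) or `|sum F|^2`
(correlated). A Crank–Nicolson time-domain mode reproduces the reference
protocol (0.0625 ms steps, 1.2 s runs, first 0.2 s discarded) for
protocol-level checks; the frequency-domain solve is the canonical oracle.
Chains import/export as plain TSV segment tables; branched morphologies
are out of scope.

## EEG composition

Only the infinite homogeneous-medium weight
`cos(theta)/(4 pi sigma r^2)` is implemented; realistic head models enter
as user-supplied abstract weights, which suffices because the population
argument needs only the factorization of each source into weight times
dipole moment. Uncorrelated dipoles add in power, fully correlated ones
in amplitude; either way a power law shared by the sources passes to the
compound PSD exactly.

## Problem sizes and defaults

The default fixture is `d = 2 um`, `D = 20 um`, `l = 1 mm`,
`R_m = 3 Ohm m^2`, `C_m = 0.01 F/m^2`, `R_i = 1.5 Ohm m` — chosen to
realize the canonical dimensionless point `b = 0.2`, `L = 1`,
`tau = 30 ms`, `lambda = 1 mm` — with white input of 1 fA^2/Hz at
2 sources/um^2 on soma and stick. Test and acceptance runs use 200–800
compartments, 2 000–10 000 Riemann segments, 50–60 s noise syntheses and
frequency grids of 30–60 points per decade; these sizes put every
cross-check several times below its tolerance while keeping the whole
suite in the seconds range.

## Known limitations

The model omits active conductances (their linearized effect on PSDs is
confined to low frequencies), conductance-based noise coupling, branched
and tapered dendrites, frequency-dependent coherence models beyond
user-supplied functions, and near-field extracellular potentials. The
synthetic slope maps and scenarios characterize the model itself; how far
a real neuron follows them depends on morphology and on the actual noise
source composition, which the mixed-noise scenario only illustrates.
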
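# Methods

## Model and notation

A center is observed from calendar time t = 0 (all times in days). Subjects
arrive by a Poisson process with rate ψ; subject *i* enters at S_i, carries
covariates Z_i, and fails at chronological time T_i = S_i + X_i or is
right-censored at R_i. The null model is a Cox-type hazard
h_i(x) = h0(x) exp(Z_i'β) with known baseline h0 and coefficients β; "known"
means estimated beforehand on data accepted as in control (estimating the
Cox model itself is deliberately outside this package — any survival
library produces the `RiskModel` inputs). A subject contributes the at-risk
indicator Y_i(t) = 1{S_i ≤ t ≤ min(T_i, R_i)}, so its cumulative intensity
is Λ_i(t) = exp(Z_i'β) H0(clamp(t − S_i, 0, follow-up)): zero before entry,
frozen after exit, with no re-entry. Under deterioration the hazard is
multiplied by exp(θ) ≥ 1.

Baselines: exponential (rate per day), Weibull (shape/scale), or a
tabulated step cumulative hazard, linearly interpolated between knots and
extrapolated beyond the last knot at the last segment's slope (equivalently
a constant hazard equal to the last segment's). H0(0) = 0 is enforced. A
step baseline that is flat at zero near the origin can produce a failure
with Λ_i = 0, which makes the hazard-ratio MLE unbounded; the charts then
require an MLE cap, and the code raises a configuration error otherwise.

## Chart statistics

With N(t) the failure count and Λ(t) the total cumulative intensity, the log
likelihood ratio for a hazard increase from the start of monitoring is
θ̂N − (e^θ̂ − 1)Λ with θ̂ = max(0, log(N/Λ)) — the CGI statistic. The CGR
chart maximizes the same expression over suffixes {ν, ν+1, …} of subjects in
entry order (the unknown first affected patient); the empty suffix
contributes 0, so the chart is nonnegative. The cap exp(θ̂) ≤ c (default
none; 6 in the registry application the charts come from) is applied to
each suffix estimate separately.

There is no recursion over time for CGR — the suffix scan is repeated at
each evaluation time. The reference implementation is a vectorized scan per
time point, with a numba-compiled inner loop for constant-hazard streams
(long in-control simulations); both are verified equal to an exhaustive
per-suffix Python oracle to 1e−12.

The BK chart fixes θ1 > 0 and maximizes over an unknown calendar
changepoint. Because U(t) = θ1 N(t) − (e^θ1 − 1)Λ(t) jumps by exactly θ1 at
failures and decreases continuously in between, BK(t) = U(t) − inf_{s≤t}U(s)
with the infimum attained at 0 or at a pre-failure left limit; this yields
an O(1) per-event reflected recursion, verified against the defining
maximization on exact candidate grids to 1e−9.

All three continuous-time charts increase only at failure times, so
detection uses the chart values at (distinct) failure times; tied failure
times are processed together, giving one chart value per distinct time.
Values between failures are available for plotting by direct evaluation.

The discrete-time baselines follow the standard risk-adjusted
constructions: the Bernoulli CUSUM scores each subject once, `window`
(default 365) days after entry, with the Bernoulli log likelihood ratio at
odds ratio e^θ1, applied subject-by-subject with reflection at zero on a
30-day evaluation grid; the funnel plot compares a center's window failure
count against the upper one-sided limit of the null count, by a normal
approximation to the sum of independent Bernoulli(p0_i) (a plain binomial
at the mean probability as the "exact" option; an exact treatment of
heterogeneous p0_i would need the Poisson-binomial and changes little at
funnel sample sizes).

## ARL approximations

The Fisher information of the observation scheme is
I(θ, t) = ψ ∫0^t E_Z[1 − exp(−e^θ e^{Z'β} H0(s))] ds. For an exponential
baseline without covariates the closed form
ψ(t − (1 − e^{−e^θ λ t})/(e^θ λ)) is used; anything else goes through
adaptive quadrature, with the covariate expectation taken over discrete
atoms exactly or by Monte Carlo with a fixed seed (20220919) and 10^4
draws. The quadrature path is validated against the closed form to 1e−6
relative.

Equating the chart's deterministic drift to h gives the out-of-control ARL
approximations quoted in the README. The roots are bracketed starting from
[ε, 1 year], doubling the upper end until a sign change (the left side is
continuous, zero at t = 0 and unbounded), then refined by Brent's method to
1e−10 relative tolerance. For θ = 0 no drift approximation exists; the
in-control ARL is a Monte-Carlo quantity. When θ1 is misspecified the BK
drift coefficient is strictly below the CGI coefficient whenever the BK
validity condition holds, so the BK approximation can never undercut the
CGI bound.

Under θ = 0 the scaled statistic t·CGI(t) is asymptotically
½·δ0 + ½·Gamma(shape ½, scale t): the MLE sits on the boundary whenever
N(t) ≤ Λ(t), which happens with probability → ½ (N − Λ is a mean-zero
martingale), and conditional on a positive value the Gamma law applies.
`cgi_null_distribution` returns the Gamma component; the test suite checks
both the zero mass and a Kolmogorov–Smirnov fit of the positive part
(2200 in-control replicates at ψ·t ≈ 2000, α = 0.01).

## Synthetic data

The generator emulates the monitoring setting the charts are built for and
nothing more: homogeneous Poisson arrivals; independent covariate
components (Bernoulli or normal) when risk adjustment is studied; failure
durations drawn by inverting the scenario cumulative hazard
m(·) exp(Z'β) H0(x). The deterioration multiplier m implements four
scenarios: in control, raised from the start, raised from patient ν onward,
or raised for everyone at risk from calendar time s (a piecewise cumulative
hazard whose kink at x = s − S_i the inversion handles analytically for
exponential baselines and by the interpolated inverse for step baselines).
Real registries differ in ways the generator does not model — arrival rates
drift seasonally, hazards change gradually rather than at a point, failures
can cluster through shared causes, and covariates are neither independent
nor stationary — so passing tests certify the charts against their own
model assumptions, not against such misspecification.

Randomness discipline: one root seed; replicate r, time-chunk k use the
child stream SeedSequence(seed, spawn_key=(r, k)), with arrivals drawn as a
Poisson count plus sorted uniforms per 4-year chunk. Consequences, both
tested: adding replicates or extending the horizon never reshuffles earlier
data, and a run simulated until signal in chunks equals the same run
evaluated in a single pass.

Default study conditions are those of the run-length comparison the package
reproduces: ψ = 2.28/day (a large center), exponential baseline
λ = 0.002/day (about half the subjects fail within a year of entry), no
covariates, control limits 6.82 / 8.35 / 7.73 for BK(ln 1.4) / BK(ln 1.8) /
CGR–CGI, whose in-control ARLs are all near 15 years.

## Calibration and studies

Two calibration contracts are provided. The type-I-error limit is the
empirical (1 − α) upper order statistic of per-center chart maxima over the
monitoring horizon across n in-control replicates, so a fresh in-control
center signals within the horizon with probability ≈ α. The ARL limit is
found by bisection on h over a fixed pool of simulated in-control runs,
each stored as its sequence of running-max increments: the estimated ARL
(mean first crossing, non-crossing runs counted at the time cap) is then a
nondecreasing step function of h and the same pool serves every candidate,
making the bisection exact and monotone by construction.

Run-length studies report mean, SD and median of the detection times of the
runs that signalled within a hard cap (default 40 years), with the
non-signalling runs counted separately as censored. The detected-only
convention matters only for in-control rows, where the run-length
distribution is roughly exponential with a mean near the cap's order of
magnitude; it is the convention under which the published in-control
mean/median are recovered (a capped-inclusive mean sits ~10–15% higher and
an uncapped mean ~25% higher for the BK chart at ln 1.4). For
out-of-control rows censoring is void and the conventions coincide. CGR
specs are evaluated as CGI on out-of-control rows — pathwise CGR ≥ CGI
makes the CGI run lengths an upper bound while avoiding the suffix scan —
and as the CGR chart itself in control.

Two further conventions the replication fixed empirically: the published
out-of-control CGI rows correspond to the *unrestricted* statistic (the cap
hardly binds once θ̂ has converged), while the in-control CGR behaviour at
h = 7.73 corresponds to the *capped* (exp(θ̂) ≤ 6) chart — without the cap
the suffix maximization turns any near-instant failure into a spike of
height ≈ −ln Λ_i, and the in-control mean run length collapses to ~1450
days. The in-control row for BK(ln 1.8) is not recovered under any
convention tried (detected-only ≈ 6300 vs the published 5478) and is
documented as a residual gap; it does not affect the reproduced quantities.

Problem sizes used by the test suite and the acceptance script — n = 3000
replicates for out-of-control means, n = 200 for the in-control BK mean,
n = 120/24 pools for ARL calibration, 2200 replicates for the null-law
check — keep the full suite in the low minutes on one CPU while leaving
Monte-Carlo error well inside every tolerance checked.

## Known limitations

Right censoring only (no left truncation beyond entry, no competing risks
or frailties); one-sided charts (deterioration only); fixed control limits
(no time-varying limits); per-center detection with no multiplicity
adjustment across centers; the funnel "exact" option uses a binomial at the
mean probability rather than the Poisson-binomial; step baselines need an
increasing tail segment to be invertible for simulation.
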
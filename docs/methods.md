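# Methods

## Model

Two layers of `N` neurons each (LGN relay cells and V1 cells) have their
receptive-field centres spread uniformly over `[-L, L)`.  The stimulus — a
fixated dot at `x_c` — drives LGN cell `j` as a homogeneous Poisson process
with rate

    R_j = A exp(-d(x_j, x_c)^2 / (2 sigma1^2)),

where `d` is the distance on the ring of period `2L` (the profile is
extended periodically so the finite network has no boundary), `A` is the
stimulus brightness in Hz and `sigma1` the tuning width.  Each LGN cell
projects to every V1 cell with weight

    W_ij = exp(-d(x_i, x_j)^2 / (2 sigma2^2)),

peak-normalised to 1; the overall synaptic scale is carried by the maximal
conductance `g`.

V1 cells are leaky integrate-and-fire units: between input events the
membrane potential relaxes to the resting value,
`dV_i/dt = (V0 - V_i)/tau_m`; an LGN spike from cell `j` arrives as a
delta-coupled conductance kick

    V_i <- V_i + g W_ij S_j (VE - V_i),

which is the instantaneous limit of a conductance pulse toward the
excitatory reversal potential `VE` and keeps `V < VE` for any `g W S <= 1`.
When `V_i` crosses the threshold `Vth` the cell emits a spike and resets to
`Vreset`; there is no refractory period, no recurrent coupling, no
inhibition and no transmission delay.

### Short-term depression

Every synapse from LGN cell `j` shares one presynaptic strength
`S_j in (0, 1]`.  Each spike of cell `j` is transmitted at the current
strength and then multiplies it by the depression factor `f` (0 < f < 1);
between spikes the strength recovers, `dS/dt = (1 - S)/tau_d`.  Under
Poisson firing at rate `R` the stationary mean of this jump process is

    S_ss(R) = 1 / (1 + (1 - f) R tau_d),

(`R` in Hz, `tau_d` in seconds in this formula).  The expression is exact,
not a high-rate approximation: Poisson arrival times are independent of the
pre-spike value of `S`, so the stationary mean solves
`(1 - <S>)/tau_d = (1 - f) R <S>`.  The implementation treats a long
event-driven simulation of the two update rules as ground truth and the
closed form is tested against it (2 % at rates 10–200 Hz).

### Default parameters

| parameter | default | meaning |
|---|---|---|
| N | 1000 | neurons per layer |
| L | 10 | half-extent of the ring (dimensionless position units) |
| tau_m | 20 ms | membrane time constant |
| V0 | -70 mV | resting potential |
| VE | 0 mV | excitatory reversal potential |
| Vth | -55 mV | spike threshold |
| Vreset | -58 mV | post-spike reset |
| g | 0.15 | maximal synaptic conductance (dimensionless) |
| f | 0.75 | per-spike depression factor |
| tau_d | 300 ms | depression recovery time constant |
| A | 100 Hz | stimulus brightness (LGN rate amplitude) |
| sigma1 | 1.5 | input tuning width |
| sigma2 | 1.5 | weight tuning width |
| dt | 0.1 ms | integration step |

The membrane constant `tau_m` and recovery constant `tau_d` are
configuration defaults in the physiological range for thalamocortical
synapses; the qualitative results do not depend on them (the robustness
sweeps vary both).

## Numerical scheme

The integrator is clock-driven with step `dt`: LGN spikes are generated as
Bernoulli(`R_j dt`) events per bin (the probability is capped at 0.1 and a
smaller `dt` demanded otherwise), all spikes inside a step are applied at
the step boundary in ascending presynaptic index, and the threshold test
runs once per step after the kicks.  Because both the leak and the
recovery are exact exponentials, the kernel jumps over event-free steps in
closed form, which is bit-identical to stepping through them.  Membrane
crossings can only happen at kick times (the leak target `V0` is
subthreshold), so no crossings are missed.  Halving `dt` changes the
acceptance quantities well within their tolerances.

Seeding: one master seed expands through `SeedSequence(entropy=seed,
spawn_key=(segment, neuron))` into independent substreams, so an identical
(parameters, schedule, seed) triple reproduces spike trains bit-for-bit,
and changing `N`, the number of runs, or the schedule length never
reshuffles unrelated streams.

## Protocol and response statistics

A run fixates at `center0` for `t_fix = 2000 ms` (at least five recovery
time constants, enforced, so the synapses reach their depressed steady
state), then displaces the input profile by `delta_M` in a single step —
the microsaccade, whose finite time course is ignored — and records
`t_post = 500 ms` more.  The population response is the total V1 spike
count in a moving bin of width `T = 50 ms` sliding by 1 ms.  From the
trace: *baseline* = mean count over the 500 ms before the displacement,
*peak* = maximum count in the 300 ms after it, *change* = peak - baseline,
*effectiveness* = change/baseline.  Bins straddling the displacement are
excluded from both windows; a zero baseline yields an explicit
undefined-effectiveness sentinel rather than a number, and such runs are
excluded from sweep averages.  The 300 ms peak window covers the transient
comfortably: the response peaks about one bin width after the displacement
and decays on the re-depression timescale
`1/((1-f) R + 1/tau_d)` (~40 ms at 100 Hz).

### Peak estimation across runs

The displacement is time-locked, so run-averaged statistics are computed
by averaging the response traces across seeds first and then reading
baseline and peak off the mean trace.  Taking the maximum of each noisy
single-run trace and averaging the maxima instead carries a systematic
upward bias of order two to three standard deviations of a bin count —
a displacement-free control then reports a spurious "effectiveness" of
several percent, which buries the genuine transient at wide tuning and
destroys the power-law tail.  Per-run summaries (and the mean of per-run
effectiveness ratios) are still computed and reported alongside for
comparison; standard errors always come from the per-run scatter.

## Mean-field theory

With depressing synapses the steady synaptic drive from LGN cell `j` is
proportional to `R_j S_ss(R_j)`.  Assuming synapses add linearly and V1
output is proportional to its summed input, the baseline is proportional
to `B = sum_j R_j S_ss(R_j)` and the transient peak — displaced rates
against the still-depressed strengths — to
`P = sum_j R'_j S_ss(R_j)`, giving the mean-field effectiveness
`(P - B)/B`.  Expanding in `delta_M`: the first-order term vanishes
because the rate profile and the strength profile are both even about the
fixation point, and the quadratic term gives

    effectiveness ~= k delta_M^2 / sigma1^2,

with `k` independent of both `delta_M` and `sigma1` (the additive offset
is zero because the effectiveness vanishes for very wide tuning).  The
exponent claims (-2 in `sigma1`, +2 in `delta_M`) are tested on the exact
discrete sums; the closed form is the asymptotic law, and its prefactor is
fitted from the sums by least squares rather than re-derived symbolically.

The asymptotic law describes an unbounded line.  On the default ring
(`L = 10`) the `sigma1 = 6` Gaussian already wraps — its value at the
antipode is a quarter of the peak — which steepens the apparent exponent
to about -2.2.  `meanfield_exponents` therefore widens the ring to
`L >= 7 sigma1_max` at fixed neuron density before evaluating the sums
(the periodic extension exists precisely to remove boundary effects);
on the widened ring the slopes are -2.000 and +2.000 to four digits.

## Study conditions and problem sizes

The simulated sweeps behind the power-law and saturation results use 20
runs per grid point for the exponent fits and the `sigma1` grid
{1.5, 2, 2.5, 3, 4, 6} at a fixed displacement `delta_M = 1.2` — small
against every grid width, far below saturation.  Sweeps run at
`N = 500` neurons per layer: the exponent is insensitive to `N` as such,
but the per-cell synaptic drive grows with neuron density, and at full
density the drive-increasing perturbations (larger `g` or `A`) push V1
deep into a compressive regime where population output is no longer
proportional to synaptic input and the fitted width exponent steepens by
0.2-0.4; at `N = 500` the network stays in the proportional operating
regime the power-law prediction assumes.  The brightness robustness
check raises `A` (100 → 120) rather than lowering it: dimming to
`A = 60` at this displacement drops the wide-width transients below the
20-run noise floor.

A single-sweep exponent fit inherits the heavy-tailed per-point noise of
the trace maxima (seed-to-seed spread ~0.2 on the slope), so the
reported exponents are means over independent replicate sweeps — each
replicate a complete sweep at 20 runs per point — which tightens the
estimate without altering the per-sweep protocol.
The `delta_M` power law is fitted at `sigma1 = 1.5` on the grid
{0.8, 1.2, 1.6, 2.0, 2.4}, all far below the measured saturation
threshold (~7 at this width) and with transients large enough to clear
the noise floor discussed below.  Qualitative structure checks
(saturation ordering, brightness linearity) use 10 runs per point.

### Fit range for the width law

The `delta_M^2 / sigma1^2` law describes an unbounded line, and the exact
mean-field sums confirm it only while the rate profile is genuinely
Gaussian on the ring.  At `sigma1 = 6` on the `L = 10` ring the periodic
image of the profile contributes a quarter of the peak rate at the
antipode; the exact sums there steepen the apparent log-log slope from
-2.02 (over `sigma1` in [1.5, 4]) to -2.3 (full grid) — a property of the
finite ring, not of the law.  The width-law fits therefore declare the
scaling regime `1 < sigma1 <= L/2.5` (wrapped image below ~5 % of peak);
all grid points are simulated and reported, and the fit uses the points
inside the declared range.

### Noise floor

All V1 cells share the LGN input, so the population count in a `T = 50 ms`
bin inherits the relative fluctuation of the total LGN spike count in that
bin (about 1-2 % at `A = 100`, `N = 500`); averaging 20 runs leaves a few
tenths of a percent, and reading a maximum over the peak window adds an
upward bias of roughly one standard deviation.  Displacements well below
one tuning width produce transients smaller than this floor at the wide
end of the grid — a displacement-free control yields the same reading —
which sets the lower bound on usable `delta_M` at 20 runs and is the main
reason the per-run maximum estimator (see above) is unusable for the
power laws.

## What the generator emulates — and does not

The synthetic stimulus is a single stationary dot with an instantaneous
displacement: no finite microsaccade speed or duration, no drift or
tremor, no retinal adaptation, no stimulus structure beyond a Gaussian
luminance profile, and Poisson LGN statistics without refractoriness or
bursting.  The network is purely feedforward with one depression variable
per afferent: no recurrent or inhibitory circuitry, no facilitation, no
multi-timescale depression, no conduction delays.  Passing tests
demonstrate the mechanism — depression-sensitised transients obeying the
stated scaling laws — in this idealised setting; they do not certify
quantitative predictions for biological V1 responses.

## Numerical and design choices

- Kick-then-depress order on each presynaptic spike: the spike that
  depresses a synapse is transmitted at the pre-spike strength.
- One depression variable per presynaptic cell (depression is
  presynaptic), shared by all outgoing connections.
- Weight matrix peak-normalised to 1; `g` carries the scale.
- Neuron placement `-L + k (2L/N)`, endpoint `+L` identified with `-L`.
- Ties in bin windows: a bin covers `[t - T/2, t + T/2)`; baseline and
  peak windows keep only bins entirely inside them.
- Saturation detection: plateau = mean peak of the top three grid points;
  threshold = smallest `delta_M` reaching 95 % of the plateau; flagged
  not-reached when the top tail is not internally flat at that fraction or
  the last point falls below 95 % of the running maximum.
- Power-law fits are ordinary least squares on log-log pairs, restricted
  to `sigma1 > 1` for the width law.

## Known limitations

- The proportionality of V1 output to summed input is an approximation:
  with strong drive the leak subtracts an input-dependent offset, so
  simulated effectiveness is not numerically equal to the mean-field value
  (the theory is tested as a scaling law and a correlation, not an
  identity).
- At wide tuning the finite ring wraps the rate profile; simulated sweeps
  on the default ring inherit a mild steepening of the width exponent.
- The moving-bin maximum smears the transient over the bin width, so
  measured effectiveness underestimates the instantaneous rate change by
  a roughly width-independent factor.
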
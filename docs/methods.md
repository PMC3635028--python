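# Model and methods

`antlobe` simulates a scaled-down locust antennal lobe (AL): 90 excitatory
projection neurons (PNs) and 30 inhibitory local neurons (LNs), each a
single-compartment conductance-based cell, randomly wired with
cell-type-specific probabilities, driven by Poisson-modeled olfactory
receptor input, and read out with a set of windowed spike-correlation
statistics designed to detect *temporal binding*: odor-specific PN subsets
whose members co-fire within 10-20 ms on every cycle of the network's
~20 Hz oscillation.

## Membrane and current models

Both cell types obey

    C_m dV/dt = -g_L (V - E_L) - sum_j I_j - I_GABA - I_slow - I_nACh + I_input

with `C_m = 1 uF/cm^2`, `g_L = 0.3 mS/cm^2`, and `E_L = -64 mV` (PN) or
`-50 mV` (LN).  Intrinsic currents are of Hodgkin-Huxley form
`I_j = g_j m^M h^N (V - E_j)`:

| cell | current | g (mS/cm^2) | E (mV) | gates |
|------|---------|------------|--------|-------|
| PN | I_Na | 120 | +40 | m^3 h |
| PN | I_K | 3.6 | -87 | n^4 |
| PN | I_A | 1.43 | -87 | m^4 h |
| LN | I_Ca | 5.0 | +140 | m^2 h |
| LN | I_CaK | 0.045 | -95 | m |
| LN | I_K | 36 | -95 | n^4 |

Intracellular calcium follows `d[Ca]/dt = -A I_Ca - ([Ca] - 0.00024)/150`
with `A = 0.0002 mM cm^2/(ms uA)`; the calcium-dependent potassium
activation is `m_inf = [Ca]/([Ca]+2)`, `tau = 100/([Ca]+2) ms`, which
produces LN spike-rate adaptation on the 100-200 ms scale.

### Kinetic identification

The A-current and I_Ca steady-state curves and the A-current time constants
use the printed Huguenard-McCormick-type expressions.  The remaining
kinetics are under-determined and were identified against the cells'
documented phenotypes, in this order of authority: PN sodium spikes ~3 ms
wide (at a -40 mV threshold), LN calcium spikes ~25 ms wide (at -30 mV)
with 0 mV-crossing peaks and 100-200 ms adaptation, spontaneous PN rates of
2-4 spikes/s under background drive, odor-driven PN rates of 10-40
spikes/s, and a GABA-dependent ~20 Hz population oscillation.

* **PN Na/K** use Traub-Miles rate functions with per-gate threshold
  shifts: Na activation -48 mV, Na inactivation -50 mV, K -58 mV.  The
  deeper K shift raises rheobase to ~7 uA/cm^2 and softens the onset
  firing rate.  K **deactivation** below -55 mV is slowed 20-fold, which
  deepens and prolongs the after-spike hyperpolarization and caps
  repetitive firing near 50 spikes/s; without this cap, strongly driven
  PNs free-run at 60-130 spikes/s and high-rate coincidences swamp the
  synchrony statistics.  Classical squid-axon kinetics were tested and
  rejected: they clamp the LN silent at any drive and give 4.2 ms PN
  spikes.
* **LN I_Ca inactivation** uses a bell-shaped time constant
  `tau_h = 5 + 90/(exp((V+45)/10) + exp(-(V+45)/14)) ms` — fast
  inactivation at the spike plateau (~6 ms), fast recovery at rest and
  under inhibition (~20 ms), slowest near threshold.  The printed-form
  two-exponential evaluates to 0.03-0.09 ms across the physiological range
  (abolishing calcium spikes outright), so the shape was re-identified
  from the phenotype.
* **LN delayed rectifier**: `n_inf = 1/(1+exp(-(V+10)/3))`,
  `tau_n = 8 + 20/(1+exp(-(V+35)/5)) ms` (slow above threshold, fast
  deactivation below).  A steep, high-threshold, slow rectifier is the
  only family found (by grid and random search over >5000 candidate
  kinetics) that yields self-terminating ~25 ms spikes at the printed
  g_Ca/g_K: low-threshold or fast rectifiers either clamp the upstroke or
  repolarize within 3-7 ms, and the I_Ca steady-state curves leave a
  window current that otherwise locks the cell at a depolarized plateau.
  The spike peak reaches ~+45 to +110 mV depending on drive, higher than
  a graded calcium spike should peak; this is a known cosmetic limitation
  without functional consequence (GABA release saturates, and events are
  detected at 0 mV either way).

## Synapses

* **Fast GABA** (LN->LN 0.3, LN->PN 0.36 mS/cm^2, E = -70 mV): continuous
  release `T = 1/(1+exp(-(V_pre+20)/1.5))` driving
  `dO/dt = 10 (1-O) T - 0.16 O`.
* **Nicotinic ACh** (PN->LN 0.045, PN->PN 0.009 mS/cm^2, E = 0 mV): a
  0.3 ms transmitter pulse (T = 0.5) on each presynaptic upward 0 mV
  crossing; `dO/dt = 10 (1-O) T - 0.2 O`.
* **Slow inhibition** (LN->PN 0.36 mS/cm^2, E = -95 mV): the same pulse
  drives `dR/dt = 0.5 (1-R) T - 0.0013 R`, `dG/dt = 0.1 R - 0.033 G`, and
  the current gates on `G^4/(G^4 + 100)` of G summed over afferents.
  With the mean LN->PN in-degree (~5 afferents) firing 20 Hz volleys, the
  Hill factor crosses one half at about the third presynaptic spike; the
  current reaches steady state several hundred ms after odor onset.

Channel state is stored once per presynaptic neuron (the kinetics depend
only on presynaptic variables), and postsynaptic sums run over the wiring
diagram; this is exactly equivalent to per-synapse bookkeeping.  Event
re-arm is 2 ms for PNs and 10 ms for LNs — a broad LN calcium spike can
dip below 0 mV mid-plateau, and a shorter re-arm would double-trigger
slow-receptor pulses.  Slow synapses share the fast LN->PN adjacency, so
every PN receives proportional fast and slow inhibition.

## Wiring and variants

Directed Bernoulli wiring: p(PN->PN) = p(PN->LN) = 0.1, p(LN->LN) = 0.25,
p(LN->PN) = 0.15; no autapses.  Seven functional variants scale
conductances on one fixed diagram: intact (I), no GABA (NG), doubled and
tripled GABA (2X, 3X), no slow inhibition (NS), and NS with doubled or
tripled GABA.  By default the GABA scaling applies to LN->PN synapses
only: rescaling LN->LN inhibition changes LN firing itself, which
re-routes the manipulation through the slow pathway (removing all GABA
*disinhibits* LNs, raises slow inhibition, and lowers PN rates — the
opposite of a GABA blockade's direct effect).  A switch restores scaling
of both connection types.

## Input model and calibration

Background: every PN receives an independent 3500 events/s Poisson train,
0.0654 uA per event; LNs receive none.  Odor: 36 PNs and 12 LNs receive
the superposition of 200 x 35 events/s trains (7000 events/s), 0.01743 uA
(PN) or 0.01667 uA (LN) per event, rate-modulated by the stimulus
envelope: Gaussian rise over 400 ms from onset (t_o = 1 s), plateau to
offset (t_d = 3.5 s), root-exponential decay after.  Each event injects a
rectangular current pulse of duration `TAU_IN = 1 ms` scaled by a single
global gain `INPUT_GAIN = 20.4` (dimensionally the inverse membrane area,
~0.05 cm^2).  The (tau, gain) pair is the one calibration of the package:
it was fixed once so that uncoupled PNs under background drive fire
2-4 spikes/s, and it simultaneously places the odor-driven input just at
PN rheobase — stimulated cells are gated by network inhibition rather
than free-running, which is the regime temporal binding requires.

## Simulation

Explicit forward Euler at dt = 0.01 ms, all state advanced synchronously;
spikes are upward 0 mV crossings.  Halving dt changes spike counts on a
driven 2 s network trial by < 5%.  Trials derive independent substreams
from (master seed, trial index) via a counter-based seed sequence; the
wiring seed is separate so variants share a diagram while trials vary.
The LFP proxy is the mean PN membrane potential, recorded at 0.1 ms and
analyzed by periodogram; the intact network shows a ~18-20 Hz peak in the
first 500 ms after onset that weakens by 1-1.5 s and collapses (power
ratio ~10-50x) without GABA.

## Statistics

For a conditioning neuron i, a w = 20 ms window is centered at every spike
of i inside the analysis epoch (default: 1 s from odor onset, pooled over
trials; windows clipped at trial edges; one target spike can satisfy many
windows).  P_{S|i} is the fraction of windows containing at least one
spike of every member of S.

* **Synchrony ratio** (ordered triplets): `SR = P_{j,k|i}/(P_{j|i} P_{k|i}) - 1`,
  computed only when both pairwise conditionals exceed 0.5; bounded in
  (-1, 1); zero under conditional independence, insensitive to rate and
  to pairwise-only correlation.  An unordered triplet is reported at a
  threshold if any of its orderings passes (switchable to all).
* **Binding index** (unordered triplets/quadruplets): minimum over members
  of the leave-one-out joint conditional; a direct synchrony measure that
  is also high for independent firing at high rate (for a homogeneous
  Poisson triplet at rate r, BI ~ (1-exp(-r w))^2).
* **Symmetric difference ratio** between PN subsets (n = larger, k =
  smaller, s = shared): `SDR = 2(k-s)/(n+k)`; 0 for identical sets,
  -> 1 for disjoint equal-size sets; insensitive to the cardinality
  difference.
* **Event counting**: disjoint synchronous events of a tuple by a greedy
  forward scan with spike consumption, so a burst is one event.
* **KC readout**: a detector fires when >= 9 of its 13 subset PNs spike in
  a sliding 10 ms window, with a 10 ms dead time (the model gives no
  refractory rule; one window is the natural choice).  Subsets are pooled
  triplet unions; when a fixed BI threshold is not attainable at reduced
  scale, the threshold is bisected from 0.65 until the pooled subset has
  ~13 members, mirroring the subset-size convention of the readout
  analyses.
* **Scrambling control**: per trial and member, spikes inside the first
  500 ms of the response are redrawn uniformly (counts preserved),
  destroying spike timing but not rates.
* Disinhibited PN: 1-s odor-evoked rate at least doubled after removing
  slow synapses (same wiring/odor/seeds); a silent cell that becomes
  active counts (any positive rate at least doubles zero).

## Synthetic fixtures

The fixture generator produces spike trains with known correlation
structure so every statistic is testable without the simulator:
independent Poisson; master events with independent per-member
participation ("pairwise-only": strong 2-point correlation, SR ~ 0);
all-or-none master events over a weak Poisson background
("triplet-correlated": the background dilutes pairwise conditionals below
one while joint co-firing survives, so SR > 0); and 20 Hz cycle-locked
firing.  Jitter is truncated at half the default analysis window so
correlated events stay detectable.  These fixtures emulate stationary
rate/correlation structure only — no envelope dynamics, no adaptation, no
inhibition — so metric tests on them validate the statistics, not the
network model.

## Problem sizes

The packaged reproduction protocols and test suite run at reduced scale on
one core: 2.2 s trials (onset + 1 s analysis epoch + margin) instead of
10 s, 5-20 trials instead of 80, and a single wiring realization.
Extracted triplet *counts* at a fixed threshold are wiring- and
scale-dependent and are treated as qualitative; rates, spectra and
fractions are stable at these scales (seed-to-seed spread of a few
percent for rates, ~0.03 for the disinhibited fraction).

## Known limitations

* Two acceptance-level quantities fall short of the model's nominal
  behavior at this operating point.  (1) The intact network suppresses
  some stimulated PNs onto a 4-9 spikes/s continuum rather than
  bimodally silencing them, so the *minimum* active stimulated rate sits
  below the nominal 10 spikes/s floor even though the population mean and
  the upper edge are in band.  (2) Absolute binding-index values of
  genuinely locked triplets peak near 0.4-0.55 rather than 0.65-0.75: LN
  drive at the printed input strengths supports ~8 spikes/s per LN
  in-network, so per-cycle inhibitory volleys onto a given PN are
  somewhat patchy and cycle-participation of bound PNs is ~0.6-0.8 rather
  than ~1.  The *orderings* (binding strongest without slow inhibition,
  growing with GABA strength, onset-concentrated in the intact network)
  are reproduced; thresholded analyses therefore use the size-matched
  threshold convention described above.
* The LN spike peak overshoots (see above).
* The fixture generator does not model firing-rate nonstationarity; the
  acceptance of the statistics on fixtures does not by itself validate
  network conclusions.
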
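# Model and methods

## The model

`swarmdrop` treats a migrating *Dictyostelium* swarm as a living droplet: a
thin film of viscous "cell fluid" with height $h(x,t)$ on a substrate,
coupled to the depth-integrated bacteria quantity $b(x,t)$ (the food lawn)
and a diffusible chemoattractant concentration $c(x,t)$ sourced by the
bacteria.  In dimensionless variables the equations are

$$\partial_t h = -\partial_x Q + g\,\phi(b)\,(h - h_*),$$
$$Q = m_p(h)\,\bigl(-\partial_x p\bigr) + m_a(h - h_*)\,\partial_x \sigma_a,$$
$$p = -\tfrac{1}{\mathrm{Ca}_\kappa}\bigl(\partial_x^2 h + \Pi(h)\bigr),
\qquad \sigma_a = \mathrm{Ca}_\xi\, f(\partial_x c),$$
$$\partial_t b = -\beta\,(h - h_*)_+\, b, \qquad
\partial_t c = \tfrac{1}{\mathrm{Pe}}\partial_x^2 c + \alpha b - \delta c.$$

* **Lubrication flow with Navier slip.**  The mobilities
  $m_p = h^3/3 + \lambda h^2$ and $m_a = h^2/2 + \lambda h$ are the depth
  integrals of the parabolic velocity profile with slip length $\lambda$ at
  the floor and a stress-free free surface.  Floor friction and slip are
  reciprocal descriptions: a friction multiplier $\times k$ is implemented
  as $\lambda / k$.
* **Capillarity and the precursor film.**  $\mathrm{Ca}_\kappa =
  \eta L^4 / (\kappa H^3 T)$ is the passive capillary number (inversely
  proportional to the effective surface tension $\kappa$).  Dry substrate is
  regularized by a thin wetting film of thickness $h_* = 0.05$: the
  disjoining pressure $\Pi(h) = (\theta^2/h_*)\,[(h_*/h)^3 - (h_*/h)^2]$
  stabilizes the film and encodes a macroscopic equilibrium contact angle
  $\theta = 1$ in rescaled units.  This term is what lets necks thin,
  de-wet and pinch off without any topological surgery.  The pure-curvature
  Laplace pressure and the wetting term are kept as separate constitutive
  functions (`capillary_pressure`, `disjoining_pressure`) and combined in
  the flux.
* **Chemotactic activity.**  Gradient-following cell motion enters as an
  active stress acting like a surface-stress (Marangoni) gradient with
  amplitude $\mathrm{Ca}_\xi = \xi H T / (\eta L^2)$ and odd, saturating
  gradient response $f(u) = u / (s + |u|)$; $s$ is the receptor-saturation
  scale.  A uniform $c$ produces no force; the force comes from *spatial
  variation* of the gradient response, which is localized at the swarm
  front where the self-generated gradient lives.  The cell sensing
  threshold is purely diagnostic by default (it defines $m_{ch}$ below); an
  optional mode also gates the stress itself.
* **Growth and kinetics.**  Proliferation is film growth at rate $g$ times
  a Monod factor $\phi(b) = b/(K_b + b)$, zero on the precursor film.
  Bacteria are consumed proportionally to the local cell column; the
  chemoattractant is produced by bacteria, diffuses, and decays at constant
  rate, giving a screening length $\sqrt{1/(\mathrm{Pe}\,\delta)} = 1$
  (25.6 µm at the calibrated scales) that localizes positional information
  near the bacterial front.

Minimal monotone/saturating forms were chosen for $\phi$, $\psi$ (linear)
and $f$ because the collective behavior — travel, elongation, shedding —
depends on their qualitative shape, not their molecular detail; each is a
small named function that can be swapped.

## Why the swarm sheds

A droplet travelling on the line of bacteria consumes the lawn beneath it;
only the leading ~1–2 screening lengths feel a usable chemoattractant
gradient.  Capillarity transmits the front's active pull to the rear.  As
growth increases the volume, an increasing fraction of the mass sits in the
"blind" rear; past a critical volume the compact travelling solution is
lost (a fold of the travelling-wave branch), the rear stalls while the
front keeps moving, the neck thins to the precursor film and a clump is
deposited.  The cycle then repeats, giving periodic shedding — in contrast
to classic chemotaxis models, which shed continuously.

## Calibrated reference configuration

Dimensionless groups: $\mathrm{Ca}_\kappa = 0.10$, $\mathrm{Ca}_\xi = 25$,
$\lambda = 0.15$, $1/\mathrm{Pe} = 36$, $\delta = \alpha = 36$, $\beta = 4$,
$g = 0.065$, $K_b = 0.2$, sensing threshold $0.05$, saturation $0.2$,
$h_* = 0.05$.  In this regime the line-track scenario sheds one clump every
33.5 time units with 48.8 length units between clump centers, against a
travelling length of 4–5 units — discrete, strictly periodic clumps, not a
continuous trail.

The scales mapping model units to the laboratory are fixed by matching the
shedding period and clump spacing to the line-track measurements (one clump
per 4.6 h, 1.25 mm apart): one time unit = 0.13731 h, one horizontal length
unit = 25.6 µm, with the height unit 100 µm chosen so swarm heights land in
the observed 100–200 µm band and the swarm-boundary threshold of 30 µm is
0.3 height units.  Derived, not fitted: the travelling-phase front speed
(≈ 4.6 µm/min), the maximal travelling length (≈ 190 µm), and the
circulation period of the co-moving vortex (≈ 2.1 h).

The bundled file `swarmdrop/data/reference_params.yaml` carries the same
configuration in physical units (µm, h; viscosity normalized to
η = 100 Pa s — only dimensionless groups enter the dynamics):

| group | value | formed from | meaning |
|---|---|---|---|
| $\mathrm{Ca}_\kappa$ | 0.10 | $\eta L^4/(\kappa H^3 T)$ | viscous vs. capillary stresses (∝ 1/κ) |
| $\mathrm{Ca}_\xi$ | 25 | $\xi H T/(\eta L^2)$ | active (chemotactic) vs. viscous flux (∝ ξ) |
| slip $\lambda$ | 0.15 | slip length / $H$ | Navier slip; friction sweeps scale it reciprocally |
| $1/\mathrm{Pe}$ | 36 | $D T/L^2$ | chemoattractant diffusion (D ≈ 48 µm²/s) |
| decay $\delta$ | 36 | $\delta_{dim} T$ | chemoattractant turnover (screening length 25.6 µm) |
| production $\alpha$ | 36 | $\alpha_{dim} B T/C$ | lawn-level fixed point $c^* = \alpha/\delta = 1$ |
| consumption $\beta$ | 4 | $\beta_{dim} T$ | lawn cleared in ≈ the swarm residence time |
| growth $g$ | 0.065 | $g_{dim} T$ | sets the shedding period (calibrated) |
| $K_b$ | 0.2 | — | half-saturation of the growth response (lawn units) |
| sensing | 0.05 | threshold·$L/C$ | $m_{ch}$ blindness threshold on $|\partial_x c|$ |
| saturation $s$ | 0.2 | const·$L/C$ | half-saturation gradient of the chemotactic response |
| precursor $h_*$ | 0.05 | $h_{*,dim}/H$ | wetting-film height (5 µm) |

## Travelling-wave analysis

The quasi-steady travelling droplet of volume $V$ satisfies the first
integral $Q = U\,(h - h_*)$ in the co-moving frame, with the
chemoattractant environment closed self-consistently: $b$ is slaved to the
height profile (lawn ahead, exponentially consumed beneath at rate
$\beta\psi/U$), and $c$ solves the steady advection–diffusion–decay balance
in the moving frame.  The closure lives in one function
(`_solve_chemo_comoving`) so an alternative can be swapped in.  The
discrete system (second-order finite differences, the same flux form as the
simulator) is solved by damped Newton with a translation-freezing
multiplier, and continued in $V$ by pseudo-arclength so folds are crossed.
At the reference parameters the branch is an S-curve: a compact fast branch
($U \approx 1.4$–$1.65$), a fold at $V_{cr} \approx 5.8$, an elongated slow
branch ($U \approx 1.0$), and a second fold near $V \approx 2.8$ closing
the bistable window.  Dynamic simulations shed at leading-swarm volumes
$\approx 3.9$, inside the bistable window: growth plus the perturbation
from the trailing film triggers the compact→elongated transition before the
fold itself is reached.

Newton tolerance $10^{-10}$, at most 50 iterations, Jacobians by forward
differences refreshed every third (chord) step; arclength steps adapt
within $[10^{-4}, 0.1]$ of the volume range.

## Metrics

All quantification mirrors the light-sheet analysis rules, applied to model
or synthetic kymographs:

* boundaries: 30 µm threshold crossings (0.3 height units) of the leading
  connected region, by linear interpolation; velocities by second-order
  central differences in time;
* bacteria gradient: windowed difference over 6 cell widths (cell width
  10 µm = 0.39 length units); the minimum gradient is taken between rear
  and peak, the maximum over the whole swarm; gradient reversals smaller
  than 2 % of the peak gradient are treated as noise;
* $m_{ch}$: the mass fraction of the swarm where $|\partial_x c|$ is below
  the sensing threshold;
* shape parameter: $S = L / L_{passive}(V)$ with lengths measured at the
  10 µm cut.  $L_{passive}$ is the length of the model's own stationary
  passive droplet of equal volume, evaluated by quadrature of the
  equilibrium first integral $h'^2 = 2[C(h-h_f) + W(h) - W(h_f)]$.  For
  macroscopically large droplets this reduces to the parabolic-cap value
  $\sqrt{6V}$; at laboratory swarm sizes the attractive tail of the wetting
  potential widens the equilibrium droplet by 10–20 %, and normalizing by
  the ideal cap would mislabel every droplet as slightly elongated.  The
  simulate-to-rest test (dynamics) and the quadrature (independent route)
  agree to better than 1 %.
* shedding events: a drop of the leading-swarm length by >25 % below its
  maximum over the preceding four output intervals, co-located with a
  solver pinch detection (height below 10 µm between two super-threshold
  regions); clump volume and center from the hump left behind;
* phase: a record is "shedding" when the rear has lost positional
  information and the elongation rate exceeds twice the travelling baseline
  (lower quartile of positive elongation rates).  In imaging-style
  kymographs the information condition is a genuine bacteria-gradient
  reversal inside the swarm; the model does not transport bacteria (no
  snowplow accumulation), its $b$ profiles are monotone, so for model
  output the condition falls back to $m_{ch} > 0.3$;
* phase diagrams: for each $(\mathrm{Ca}_\kappa, \mathrm{Ca}_\xi,
  \mathrm{friction})$ the line track is run to first shedding; morphology
  is "clump" when $S$ at shedding is below 2, "extended trail" above.

## Flow field and tracks

The parabolic profile is reconstructed per column from the slip and
stress-free conditions plus the depth-average constraint $\bar u = Q/h$;
the vertical velocity follows from incompressibility.  In the co-moving
frame of a travelling wave this field is a vortex (treadmilling): surface
cells run forward at $\approx 0.4 U$, floor cells backward at
$\approx -0.7 U$.  Streamlines are integrated adaptively; the circulation
period is the return time to a Poincaré section through the vortex core,
and the outermost closed orbit defines the boundary cycle time.

Synthetic cell tracks advect virtual cells in this flow with isotropic
Gaussian random-walk motility (reflecting floor and free surface,
deterministic per seed), written as TrackMate-style tables.  The default
motility magnitude is of the order of the mean flow speed, reflecting that
individual core cells are as motile as surface cells but undirected.  The
track-averaging analysis (velocities by central differences, averaged
relative to the swarm peak over 15-min windows, bins with fewer than five
samples masked) recovers a noiseless input field to within 5 %, which is
the module's round-trip oracle.

## Synthetic kymographs

`swarmdrop.synthetic` builds imaging-like kymographs without the PDE: a
smooth hump (height ~150 µm, length ~300 µm) advancing at constant speed, a
bacterial lawn with a leading accumulation peak up to twice the lawn level
and a depleted rear, and a sawtooth variant whose collapse times and pinch
positions are known exactly.  These generators emulate the *geometry* of
side-view light-sheet quantification; they do not emulate imaging noise,
segmentation error, 3-D structure, or bacteria transport by the swarm, so
tests passing on them validate the metric implementations, not the
instrument pipeline.

## Numerical choices

* Method of lines; faces/fluxes assembled conservatively; BDF time
  stepping (adaptive, rtol $10^{-6}$, atol $10^{-8}$) with a banded
  Jacobian sparsity pattern.  The fourth-order capillary term makes the
  system stiff; with sources off the scheme conserves $\int h\,dx$ to
  round-off (zero-flux end faces, heights clamped to the precursor far
  field).
* Grid: the shedding regime is insensitive to resolution between
  $\Delta x = 0.08$ and $0.16$ (clump positions shift < 1 %); production
  runs use $\Delta x \approx 0.16$ (≈ 4 µm).  The reference acceptance run
  uses 1408 nodes over 225 length units for four shedding cycles
  (~3 minutes on one core); tests use smaller domains chosen to keep the
  full suite in tens of minutes.
* Transient undershoots of $h$ below the precursor height are tolerated by
  evaluating the disjoining pressure with a floor at $0.3\,h_*$; the
  equilibrium film next to a pressurized droplet sits slightly above
  $h_*$, and a shallow dimple below $h_*$ forms at contact lines — both are
  standard features of precursor-film models.
* Output cadence defaults to 25 model-minutes equivalent (0.5 time units in
  the calibrated units, matching the time-lapse interval of the reference
  data).

## Limitations

* Pseudo-2D: one horizontal dimension plus depth; planform fingering versus
  sheet-like trails cannot be distinguished.
* Bacteria are consumed but not advected; the experimentally observed
  leading bacteria peak ("snowplow") and gradient reversal are therefore
  absent from model kymographs (the metrics support them for synthetic and
  imaging-style input).
* The travelling-wave $c$-closure assumes a strictly steady co-moving
  environment; during rapid elongation this underestimates rear gradients,
  so the dynamic transition happens inside, not at, the bistable window.
* Material parameters are emergent effective quantities fixed by
  calibration to shedding period and spacing; they are not measured
  single-cell properties.
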
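# Methods

## Scope and design

`mmdna` analyses ensembles of B-DNA duplex snapshots containing a single
central lesion pair, and generates synthetic ensembles with exact ground
truth for every quantity the analysers measure. The generator is not a
molecular-dynamics surrogate in any energetic sense: it draws helical
coordinates from a declared distribution and rebuilds atoms from them, so
that planted effects (mean offsets, variances, breathing excursions, ion
fields) are known exactly and recovery can be tested quantitatively.

## Reduced-atom chemistry

Each nucleotide carries the heavy ring atoms of its base (9 for purines, 6
for pyrimidines), the exocyclic O/N hydrogen-bond partners, C1′, a
pseudo-O4′ and one pseudo-P; no further backbone or hydrogens. Idealized
planar base geometries are embedded in the standard reference frame
(x toward the major-groove edge, y toward the sugar, z along the stack
normal) and shipped as a versioned JSON data file. This is sufficient for
every analysis in scope — frame fitting, hydrogen bonds, χ, grooves — and
keeps builds and fits fast.

The pseudo-P sits at a fixed offset (−2.75, 8.80, 0.00) Å in its base's
frame, calibrated once so that a straight fiber-like build reproduces
canonical B-DNA cross-strand P–P separations (minor-groove minimum
~11.7 Å at register offsets −3/−2, major ~17.2 Å at +3/+4, P radius
~9.2 Å). The pseudo-O4′ is placed by an internal-coordinate (natural
extension) construction off C1′ (bond 1.42 Å, angle 108.2° to the
glycosidic N) at whatever torsion realises the requested χ.

## Helical coordinate convention

Pairs and steps are decomposed with a symmetric mid-frame scheme of the
CEHS/3DNA family: the relative rotation between two frames is written as
Rz(Ω/2−φ)·Ry(Γ)·Rz(Ω/2+φ); Γ and the hinge phase φ give tilt = Γ sin φ and
roll = Γ cos φ (buckle/propeller for pairs), Ω is the twist (opening), and
translations are read in the mid frame. The Crick frame is flipped 180°
about x before pairing; positive opening is a major-groove excursion. The
builder inverts the identical formulas, which yields the round-trip
contract checked in acceptance: build→analyze reproduces every parameter
to ≤ 10⁻⁶ over the full draw box (|translations| ≤ 3 Å, |rotations| ≤ 60°).

Two numerical choices matter. (i) The Euler pair (α, γ) is defined mod
360°; the decomposition selects the branch with Ω = α+γ ∈ (−180°, 180°],
which keeps tilt/roll signs and the mid-frame x/y axes on the builder's
branch when the hinge phase is large. (ii) Near Γ = 0 the individual Euler
angles are ill-conditioned, so the twist is taken from the in-plane 2×2
block (error O(Γ²)) below Γ ≈ 10⁻⁶ rad. No conformance to any specific
published tool's numbers is claimed — only internal exactness and the
standard sign symmetries (strand exchange negates shear, buckle, shift,
tilt), which are tested.

Global descriptors: the helical bend of a snapshot is the angle between
the mean mid-step z axes of the first three and last three included steps;
the total twist is the step-twist sum over the included range. The default
range excludes the outermost pair at each end (end fraying), i.e. steps
1–10 of a 13-mer. A curvilinear-axis bend was deliberately not
implemented; the two-window axis angle is the declared substitute, and the
step range is an explicit argument because reported per-duplex total
twists depend on it.

## χ conformers

χ is O4′–C1′–N9–C4 (purines) or O4′–C1′–N1–C2 (pyrimidines). Bins, chosen
once and applied everywhere: anti (120°, 180°] ∪ (−180°, −90°]; high-anti
(−90°, −30°]; syn (−30°, 90°]; other the remainder. The generator's
default χ target is −117° (B-form anti).

## Hydrogen bonds and pairing schemes

The reduced-atom model has no hydrogens. A donor-acceptor contact counts
as a hydrogen bond when the heavy-atom distance is ≤ 3.5 Å **and** the
angle at an idealized in-plane hydrogen is ≥ 135°. Idealized hydrogens:
sp² amines get two H at ±120° from the attached ring atom in the base
plane; ring N–H gets one H opposite the bisector of its ring neighbours.
A plain antecedent–donor–acceptor angle cutoff at 135° was rejected
during design because ideal Watson-Crick geometry itself has C–N···O
angles near 118° and would classify canonical pairs as unbonded; the
virtual-hydrogen angle is ~175° for the same geometry and discriminates
correctly.

Pairing schemes are editable YAML catalogs, one per lesion base
combination, listing donor→acceptor atom pairs across the two lesion bases
(sugar O4′ acceptors permitted). A frame is labelled with the first fully
formed scheme, ties broken toward more bonds and then catalog order;
unmatched frames fall into an `unassigned` sink, so fractions always sum
to 1. Promiscuity is the number of schemes above a reportable occupancy
(default 5%). The shipped catalogs are seed topologies (wobble pairs,
mirrored purine·purine schemes, single-bond pyrimidine·pyrimidine
contacts); they are data, not code, and carry no claim of completeness.

## Breathing

A pair is open in a frame when its opening deviates from a reference (the
canonical-control median at that position, or an explicit value) by more
than a threshold, sustained for at least `min_frames` consecutive frames
(hysteresis against single-frame noise). Defaults: 45° and 2 frames, both
config-exposed, declared here rather than taken from any published
criterion. The excursion sign assigns the direction (positive = major
groove). Occupancy, transition counts and residence times come from
run-length encoding of the state series and are tested against an
independent per-frame scan; planted excursions ≥ 2× threshold are
recovered with full recall, and ≤ 0.5× threshold excursions never fire on
noise with σ = threshold/6.

## Grooves and ions

Groove width at position i is the minimum cross-strand P–P distance over a
fixed register window minus 5.8 Å (summed phosphate radii), floored at 0;
windows are −3/−2 (minor) and +3/+4 (major), fixed by the fiber
calibration above. Positions whose window runs off the duplex are NaN,
never zero.

Cation maps accumulate counts in radial (0–16 Å × 0.5 Å) × angular
(10° sectors) bins within a ±1.7 Å slab of the local pair frame at the
chosen position, θ = 0 at the major-groove center (+x). Molarity is
count / (frames × bin volume × 6.022×10⁻⁴), an exactly invertible
conversion: Σ (M·V·6.022×10⁻⁴) equals the mean in-slab count by
construction, which acceptance checks to machine precision. The local
pair frame, not a curved global axis, defines the cylindrical system;
this is the declared substitute for curvilinear-axis maps. Color-scale
clipping (0–5 M) is presentation-only.

## Ensemble summaries

The average structure iterates superposition-to-mean until the mean
displacement is < 10⁻⁶ Å (default selection: all atoms of the interior
pairs, one trimmed per end). RMSd is evaluated after optimal rigid
superposition (SVD Kabsch with determinant correction); clustering is
average-linkage agglomeration on the pairwise RMSd matrix at a cutoff,
with the representative the medoid (minimum summed RMSd) of the largest
cluster, all ties resolved toward the lowest frame index.

Stiffness constants are univariate harmonic inverse-variance estimates,
k = k_B T/Var(x) with k_B = 1.9872×10⁻³ kcal/mol/K (k_BT ≈ 0.593 kcal/mol
at 298 K), for global bend, lesion opening and minor groove width. A full
covariance (matrix-inverse) elastic model is out of scope by design — the
analysis reports three scalar constants per duplex. Constant series flag
infinite stiffness rather than dividing by zero.

Correlations: Pearson for linear pairs, the O(n) Fisher–Lee coefficient
for circular pairs, and the (unsigned) Mardia coefficient for mixed pairs;
series are flagged circular through an explicit argument, zero-variance
series yield NaN.

## Lesion information transfer

For each (relative position, parameter) cell the mismatch ensemble is
compared with a control: means, |Δmean|, SDs, and standard errors
corrected for serial correlation through the integrated autocorrelation
time τ = 1 + 2Σρ_k, accumulated while ρ_k exceeds the white-noise band
2/√n (effective n = n/τ; naive SEs are reported alongside). The tail
probability is the empirical fraction of control frames deviating from
the control mean by at least |Δmean| (two-sided, no parametric form
assumed); the mean test is Welch's unequal-variance t with effective
sample sizes in both the statistic and the Welch–Satterthwaite degrees of
freedom. A cell is flagged when tail ≤ α (default 0.05) **and**
p ≤ α_t (default 0.01); the transfer range is the largest flagged
|position|. No multiple-testing correction is applied by default (per-cell
reporting); Benjamini–Hochberg is available behind a flag. Under the null
the p-values are uniform (KS-checked over 1000 repeats) while the joint
flag essentially never fires, because the tail criterion requires a mean
shift of order the per-frame SD, far beyond null fluctuations of order
SD·√(2/n).

## The synthetic generator and what passing tests mean

Frames are drawn from a multivariate normal over the stacked parameter
vector (block-diagonal by default) around a mean table; default per-entry
SDs are B-form-like fluctuation scales (e.g. twist 5°, roll 5.5°, opening
4°, rise 0.3 Å) at 298 K. One master seed is expanded per frame through a
counter, so identical specs are bit-identical; draws with rise ≤ 0 are
redrawn from a fresh substream, counted and warned. Planted breathing
windows override the opening of the target pair by a signed amplitude;
ion fields are Poisson point processes with intensity molarity × bin
volume × 6.022×10⁻⁴.

The generator emulates stationary Gaussian fluctuations with optional
planted structure. It does **not** emulate anharmonicity, multi-state
kinetics, backbone substates, sequence-dependent coupling between
positions (unless a full covariance is supplied), solvent structure, or
force-field physics. Passing tests therefore demonstrate that the
*measurement machinery* is exact and calibrated — not that any particular
mismatch produces any particular number in real DNA.

For the planted-transfer acceptance check, the shared noise model puts a
1.5° per-frame SD on step twists so that the planted 3.7° mean offset is a
genuine tail event of the control distribution (tail ≈ 0.014 < α = 0.05),
the regime the flag rule is designed for; with B-form-scale twist noise
(~5°) the same offset would shift the mean with overwhelming test
significance but would not be a per-frame tail event, and the tail flag
would correctly stay silent. Problem sizes used by the test-suite and the
acceptance script (10³ round-trip tables, 2×2000-frame transfer
ensembles, 10³ null repeats of 500 frames, 10⁴-frame ion fields) were
chosen so every statistical tolerance is met with wide margin at
single-CPU desk scale.

## Known limitations

- Helical bend and groove widths use declared substitutes (two-window axis
  angle; fixed-register P–P minima) rather than curvilinear-axis methods;
  absolute values are convention-dependent even though all internal
  contracts are exact.
- The reduced-atom model cannot express sugar pucker, backbone torsion
  substates (BI/BII), or protonated/tautomeric pairing variants; scheme
  catalogs are limited to heavy-atom donor/acceptor topologies.
- Base-frame fitting on planar rings is ill-conditioned out of plane:
  at 0.01 Å coordinate noise the fitted frame deviates ~0.2° (up to
  ~0.7°) from a planted rotation, dominated by the out-of-plane axes.
- The transfer statistics assume stationary, roughly Gaussian per-cell
  series; the autocorrelation correction uses a simple banded estimator of
  τ and will under-correct series with very long correlation tails.
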
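# Methods

`thermolock` studies a temperature-sensing mechanism of prion-like
disordered domains: an intramolecular antiparallel β-strand "lock" between
two short sequence segments holds the chain in a closed conformation at low
temperature; heating strengthens nonspecific sticker attraction (LCST
behaviour), melts the lock, and exposes the chain to intermolecular
interaction.  The package provides (i) a coarse-grained generator that
emulates the statistical structure of a replica-exchange simulation of such
a chain, (ii) a metric suite implementing the standard trajectory
observables, (iii) an inference stage that detects the lock from Δcontact
profiles, (iv) a forward FRET-lifetime model, and (v) label-free proteomics
enrichment statistics with a planted-truth generator.

## Coarse-grained chain model

Each residue is two beads: a backbone bead (trace) and a side-chain bead.
Residues carry a sticker–spacer category: aromatic `sticker`, `hydrophobic_spacer`,
`polar_spacer`, `flexible`.  Interactions (nm, K, kJ/mol; k_B = 0.0083144621
kJ/(mol·K); sweeps are the time unit):

* **Bonds** — harmonic, backbone–backbone r₀ = 0.38 nm, backbone–side-chain
  r₀ = 0.25 nm, k = 1000 kJ/mol/nm².
* **Angles** — harmonic on backbone triples, θ₀ = 120°, k = 1 kJ/mol/rad².
  The small constant keeps the chain flexible (IDR-like); stiffer chains
  resist the coil–globule transition the model must show.
* **Excluded volume** — purely repulsive harmonic overlap term,
  ½·400·(σᵢⱼ−r)² for r < σᵢⱼ, σᵢⱼ the sum of bead radii (0.15 backbone,
  0.20 side chain).  Finite at overlap, so Metropolis sampling tolerates
  imperfect starting structures.
* **Side-chain attraction** — quartic well −ε(T)·(1−(r/r_c)²)² for r < r_c
  = 0.8 nm.  Depths combine geometrically from per-residue epsilons
  (sticker 2.8, hydrophobic 0.9, polar 0.25, flexible 0.15 kJ/mol) and,
  when both residues are sticky (sticker or hydrophobic), are multiplied by
  the LCST factor `1 + α·(T−T_ref)/T_ref` with α = 10, T_ref = 280 K.
  This is the implicit-solvent encoding of solvent-entropy-driven
  attraction: heating strengthens hydrophobic/aromatic contacts, which is
  what makes the model an LCST polymer.
* **Lock** — between the backbone beads of each registry pair (25↔82 …
  30↔77 in the default presets), a Gaussian well of depth ε_lock·s(T)
  centred at 0.32 nm (width 0.12 nm, cutoff 0.8 nm), gated by a smoothstep
  on the local backbone extension of both partners (0.50→0.62 nm): β-ladder
  hydrogen bonds only form between locally extended strands, which keeps
  crowding-induced near-contacts in a dense globule from scoring as a lock.
  Adjacent intact rungs earn a small cooperative bonus (ε_coop = 1.5
  kJ/mol) — β-sheet hydrogen bonding is cooperative, and the product form
  suppresses isolated spurious rungs while keeping open/close kinetics
  fast.  The depth scale is ε_lock = 13 kJ/mol at T_ref with a linear
  temperature coefficient `s(T) = max(0, 1 − α_lock·(T−T_ref)/T_ref)`,
  α_lock = 2.7.

**Why the lock weakens with temperature.**  An earlier iteration used a
strictly temperature-independent well and relied on move-set entropy to
melt the lock on heating.  Extensive calibration showed this cannot work at
desk scale: between 280 and 310 K, β changes by only ~10%, so the
entropy–energy balance that must flip spans a parameter window narrower
than run-to-run fluctuations — and worse, the LCST collapse at 310 K crowds
the duplex and *stabilizes* it, inverting the intended behaviour.  In an
implicit-solvent model the physical resolution is symmetric with the LCST
term itself: backbone hydrogen bonds compete with solvent and effectively
weaken on heating, exactly as hydrophobic contacts effectively strengthen.
Both temperature coefficients are free-energy parameterizations of solvent
entropy that the model does not represent explicitly.  With this encoding
the lock melts sharply between 280 and 310 K with fast, seed-robust
kinetics (occupancy ≈ 1.0 at 280 K, ≈ 0.0 at 310 K, against the
calibration requirement of > 0.6 / < 0.3).

**Composition of the wild-type preset** (90 residues): stickers on every
third residue, hydrophobic spacers between them, polar elsewhere, a short
flexible hinge at residues 50–55, and *polar* lock segments (25–30,
77–82) with polar flanks (±3 residues).  The polar flanks matter for the
preset comparisons: sticky neighbours otherwise compete the duplex open a
few kelvin earlier in the wild type than in the sticker-weakened variant,
blurring their ordering in the melt region.  The dense sticky background is what gives a genuine coil–globule
transition over the 280–316 K ladder (sparser sticker spacings were tested
and do not collapse).  The lock segments are kept polar so their side-chain
contacts come almost entirely from the paired duplex: melting then shows
the canonical Δcontact signature — a global gain from compaction with a
localized loss at the lock segments.  Sticky lock segments were tested and
behave differently: they become contact hubs of the hot globule and *gain*
contacts on heating, hiding the lock from the Δcontact profile.

Variants: `y_to_s` lowers sticker epsilons to the polar level (lock
retained); `m1`/`m2` zero the lock energy (segment-A / segment-B mutants —
energetically identical in this model, kept as separate presets because
they are distinct constructs of the emulated experiment);
`no_lock_homopolymer` is a uniform polar chain.

## Sampling

Metropolis Monte Carlo with single-bead displacements (max 0.12 nm),
crankshaft rotations of one residue about its neighbours' axis, pivot
rotations of the shorter chain arm (max 1.2 rad; rotating the shorter arm
keeps the proposal symmetric and bounds the move cost), and rigid chain
translations for two-chain systems.  One sweep = n_beads attempted moves;
acceptance min(1, e^(−ΔE/kT)).  A discretized displacement mode (fixed
lattice steps) supports exactly enumerable toy systems.

Replica exchange: nearest-neighbour swaps attempted every 10 sweeps,
alternating even/odd pairs.  Because the Hamiltonian is
temperature-dependent (LCST and lock coefficients), swaps use the
generalized criterion min(1, exp(−[βᵢ(Uᵢ(xⱼ)−Uᵢ(xᵢ)) + βⱼ(Uⱼ(xᵢ)−Uⱼ(xⱼ))])),
which preserves per-rung Boltzmann distributions and reduces to the
textbook min(1, exp((βᵢ−βⱼ)(Eᵢ−Eⱼ))) when the Hamiltonian is shared.
Swaps exchange configurations between rungs; the replica→rung walk is
logged.  The first 20% of each trajectory is flagged as equilibration by
default (30% in the validation studies, which use short runs).

Initial structures: with a lock present, the two segments are built as a
paired antiparallel duplex and the remaining stretches as biased random
walks (the analogue of starting from a predicted folded structure); without
a lock, a plain random walk.  The lock-detection and FRET studies use the
folded start at both temperatures (the cold run keeps the lock, the hot
run melts it); the ladder-direction study starts from unbiased coils so
the per-rung trends are governed by the sticker thermodynamics — with
replica exchange the wild type re-forms its lock and compacts while the
sticker-weakened variant stays a coil, yielding monotone metric curves.  A short displacement-only quench (60 sweeps
at 120 K) anneals construction overlaps without tearing the built duplex
(global moves during the quench were found to rip it apart while relieving
overlaps).

Periodic cube of edge 7 nm, minimum-image convention, coordinates stored
unwrapped.  Note one deliberate subtlety: on a lattice whose step is
exactly half the box edge, the minimum image of a half-box separation is
ambiguous and energies stop being a function of the configuration modulo
box translations; the enumerable toy therefore uses a 3-step box.

Energy kernels are numba-compiled; energy deltas for the rigid move subsets
only evaluate terms crossing the moved/unmoved boundary, and stored frame
energies are freshly recomputed at record time (which also zeroes
incremental drift).  Identical (config, seed) gives byte-identical
ensembles.

## Trajectory metrics

Shared definitions for coarse-grained and all-atom input:

* **Side-chain contact**: minimum side-chain heavy-atom (or bead) distance
  < 0.6 nm; intramolecular pairs with sequence separation ≤ 3 excluded
  (configurable; "three adjacent residues" is read as |i−j| ≤ 3);
  intermolecular pairs have no exclusion.
* **Hydrogen bond**: donor–acceptor distance ≤ 0.35 nm and
  acceptor–donor–hydrogen angle (vertex at the donor, between D→A and D→H)
  < 30°.  Coarse beads carry no hydrogens, so CG site sets mark the
  hydrogen index −1 and the angle criterion is vacuous for those donors
  (distance-only); the full rule applies to all-atom input.  CG donors and
  acceptors are the backbone beads, with intramolecular separation ≥ 3.
* **β-strand (CG)**: residue i is strand in a frame if some partner j forms
  a rung (trace distance ≤ 0.35 nm, separation ≥ 3) together with an
  adjacent rung (i±1, j∓1) or (i±1, j±1), and both partners are locally
  extended (|trace(i−1)−trace(i+1)| ≥ 0.56 nm).  All-atom input instead
  goes through DSSP (mdtraj), strand = 'E'; the Kabsch–Sander energy
  criterion is undefined without backbone carbonyls, hence the CG ladder
  rule.
* **SASA**: Shrake–Rupley with a deterministic golden-spiral point set
  (default 960 points, probe 0.14 nm); agreement with the analytic sphere
  is ≲ 0.3% at the default density.
* **Ensemble averages**: equilibration discard, then mean with a
  block-bootstrap SE (10 contiguous blocks, 200 resamples, seeded).

## Lock detection

The Δcontact profile is the per-residue change of summed intramolecular
contact frequency between a hot and a cold ensemble (hot − cold), with
frame-bootstrap CIs.  `detect_lock` calls a lock iff (1) at least two
maximal runs of ≥ 3 consecutive residues fall below −0.6 while the global
mean Δcontact is positive, (2) some pair of such segments has an
inter-segment contact frequency ≥ 0.3 in the cold ensemble (the strongest
pair frequency of the cross block, i.e. the registry signal), and (3) the
mean β-strand probability over that pair drops by ≥ 0.2 from cold to hot.
The Δ-threshold of 0.6 was calibrated once on the generator: planted lock
residues dip by ≈ 0.8–1.9 contacts while lock-*adjacent* residues (which
lose a little contact when the duplex melts) dip by ≲ 0.65; the threshold
recovers the planted boundaries within ±1 residue.  On generated data the
detector recovers the planted 25–30/77–82 lock in ≥ 18/20 seeds and stays
silent on 20/20 no-lock runs.

## FRET forward model

Donor at residue 1, acceptor at the last residue (backbone beads); Förster
efficiency E = 1/(1+(r/R₀)⁶) per frame; predicted mean donor lifetime
τ_D·(1−⟨E⟩) under the static-frame assumption (each stored conformation
contributes a quenched lifetime; no excited-state dynamics, no instrument
response).  R₀ = 5.4 nm and τ_D = 2.6 ns are representative GFP→mCherry
literature constants, both configurable.  Predictions are meaningful as
*orderings* (cold vs hot, wild type vs lock-dead mutants), not as absolute
nanosecond values.

One caveat matters in practice: the hot wild-type ensemble samples the
*post-melt transient* — after the lock melts, the termini separate, and
only much later does the strengthening sticker attraction re-compact the
chain and re-shorten the donor–acceptor distance.  (The emulated
observable is likewise measured shortly after heating.)  The end-to-end
spread of that transient varies run to run, so lifetime orderings are
evaluated on means over five replicate simulation pairs
(`validation.fret_ordering_study`); single pairs can invert.

## Proteomics enrichment

Top-3 quantification: per protein and replicate, the mean of the three
largest peptide areas within that replicate (all if fewer; the alternative
reading — top three by replicate-averaged area — is available via
`per_replicate=False`).  Imputation: one global constant, the mean over
replicate columns of each column's minimum observed area, applied to every
missing cell after protein-level quantification.  Fold change: mean bait
area over mean control area.  Arms: `turboid` calls enrichment at log2FC ≥
1; `ipms` additionally requires Benjamini–Hochberg adjusted p < 0.05 from
an empirical-Bayes moderated t-test on log2 areas — pooled two-sample
variances shrunk toward a prior (d₀, s₀²) fitted by method of moments on
the log sample variances (the trigamma-inverse construction), statistic on
d+d₀ degrees of freedom.  The moderated test agrees with Bioconductor
limma's eBayes to within a few percent on random tables (the residual
difference is limma's finite-sample corrections in the prior fit) and to
1e−8 with an independently coded straight-line implementation of the same
formulas.

The synthetic proteome plants `n_enriched` of `n_proteins` proteins at a
true log2 effect on a log-normal baseline (log2 means ~N(20, 2), replicate
noise σ = 0.5 on the log2 scale, 4+4 replicates) with either MNAR-low
censoring (the lowest cells go missing — the mass-spectrometry-like
mechanism, default 5%) or MCAR.  At the reference setting (1000 proteins,
100 enriched at log2FC = 2) the ipms arm achieves recall ≥ 0.9 with FDP ≤
0.1, and the empirical null FDR on effect-free tables is ≤ 0.05.

## What the generator does and does not emulate

The coarse model reproduces the *statistical phenomena* analysed by the
pipeline: LCST compaction with temperature (Rg and SASA fall, contacts and
H-bonds rise from 280 to 316 K), a two-segment β-lock that is occupied at
280 K and melted at 310 K, the resulting Δcontact signature, more
intermolecular contact at higher temperature in two-chain runs, and the
FRET lifetime ordering.  It does not emulate chemistry: no explicit
solvent, no sequence beyond categories, no force-field energetics, no
realistic absolute magnitudes (contact counts, H-bond counts and lifetimes
are model units).  Passing tests therefore demonstrate that the *analysis
stages* recover planted structure from ensembles with realistic statistical
behaviour — not that the coarse model is quantitatively predictive of any
real domain.

## Problem sizes in the validation studies

The studies are sized for a single CPU: the Boltzmann toy samples 60 000
sweeps over a 3-rung ladder of a 4-bead lattice system (19 683 enumerable
states); ladder studies run 8 rungs × 9 000–10 000 sweeps of the 90-residue
chain; lock recovery uses 20 + 20 seed pairs of 4 000-sweep runs at
280/310 K; two-chain runs are 10 000 sweeps; enrichment statistics use 20
seeds of 1 000-protein tables plus 20 effect-free 2 000-protein tables.

## Known limitations

* The two lock-dead mutants are energetically identical here (both zero
  the registry energy), so their predictions coincide; the real constructs
  differ chemically.
* The lock melt is first-order-like; very near the melting midpoint
  (~295–300 K) single runs can stay kinetically on one side.  The study
  temperatures 280/310 K sit well outside this window.
* CG hydrogen-bond counts use a distance-only criterion (no hydrogens
  exist at this resolution); absolute counts are not comparable to
  all-atom values.
* The intermolecular studies use exactly two chains in one periodic box;
  no concentration series, no phase diagram.
* `mc_sweep`/`run_remd` sample equilibrium ensembles; sweep counts carry no
  physical time mapping, so only equilibrium (not kinetic) observables are
  meaningful.
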
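# Methods

## Model and assumptions

`neoqc` implements mean-field and second-order correlated energies for a
mixed quantum system of `N_e` electrons and `N_p` quantum protons. The
working assumptions:

* **Closed-shell electrons.** Spatial orbitals doubly occupied; open shells
  are rejected at validation.
* **High-spin quantum protons.** All quantum protons share one spin channel
  and singly occupy nuclear orbitals. They are identical fermions, so the
  nuclear Fock operator carries full same-spin exchange; for a single proton
  the Coulomb and exchange terms cancel exactly (no self-interaction), which
  the suite asserts. Only hydrogen nuclei may be quantum.
* **Fixed basis centres.** Nuclear basis functions sit on the quantum
  protons' geometric positions and do not move during the SCF. Electronic
  basis functions are placed on *all* centres, including quantum protons —
  the cluster function counts force this convention.
* **Coordinates** are read in Ångström and held in bohr; energies in hartree
  (1 hartree = 627.5094740631 kcal/mol); the proton mass is the CODATA value
  1836.15267343 m_e.

## NEO-SCF

The electronic problem at fixed proton density is a conventional RHF problem
with an added attractive mean field `−J[P_p]`; the nuclear problem at fixed
electron density is a high-spin HF problem with kinetic scaling `1/m_p`,
point-charge repulsion from classical nuclei and `−J[P_e]`. The driver
interleaves the two sub-SCFs (electrons first), each converged with DIIS
(error `F P S − S P F` in the orthonormal basis, start iteration 2, subspace
10), to sub-thresholds of 1e-8 au on density and gradient; the outer loop
stops when the total energy moves by less than 1e-7 hartree *and* the
electronic Brillouin gradient evaluated at the updated proton density is
below ten times the sub-gradient threshold. Divergence (energy rising by
more than 1 hartree between outer iterations) aborts with the history
attached.

**Initial guess.** The electrons are first converged with the quantum
protons as clamped point charges (i.e. the classical-nuclei RHF solution,
seeded by a core-Hamiltonian guess); each proton then starts from the lowest
eigenvector of its *site-local* block of `h_p − J[P_e]`. Two design points
matter here and were chosen after observing failure modes, not taste:
a bare kinetic-eigenvector proton guess is dominated by the most diffuse
functions and can trap the alternating minimization in spurious joint
stationary points well above the physical solution; and a *global* aufbau
over the proton Fock can double-occupy the deepest well in multi-proton
systems and start charge sloshing between sites. The clamped-RHF +
site-local scheme converges all shipped fixtures to the variationally
ordered solution (larger nuclear basis ⇒ lower energy, asserted on a
superset ladder).

## Canonical MP2 channels

Spin integration with doubly occupied electrons and singly occupied
high-spin protons gives the three channel expressions quoted in the README.
They are not taken on faith: `rspt2_oracle` enumerates all doubly excited
determinant products over spin orbitals (electrons with two spins, protons
with one shared channel), evaluates the fluctuation-potential matrix
elements by the Slater–Condon rules from full MO-basis integral tensors, and
sums `|W_0n|²/(E_0 − E_n)`. The electron-proton factor 2 (electron spin sum
over conserved-spin single×single products) and the pp antisymmetrized ¼
prefactor are confirmed by this route to ~1e-16 hartree on one- and
two-quantum-proton H2. The ep integrals carry the attractive sign
throughout, although the squared numerator makes the channel energy
insensitive to that convention. Denominators below 1e-8 au abort with the
offending index quadruple named; no regularization is applied. No frozen
core: occupied counts include O 1s.

## Density fitting

Robust (Coulomb-metric least-squares) fitting collapses to
`K̃ = Eᵀ J⁻¹ E`; the energy error is quadratic in the density residual. The
metric is Cholesky-solved; if its smallest eigenvalue falls below 1e-10 of
the largest, the solve falls back to an eigenvalue-filtered pseudo-inverse
with a warning (even-tempered sets with high angular momenta do go
near-singular, deliberately — accuracy is set by the retained subspace).
The ee and pp blocks use the unified electronic+nuclear auxiliary basis with
one shared metric; the ep block uses the nuclear fitting set alone. An
optional proximity screen zeroes ep three-index entries whose occupied and
virtual orbital centroids both lie farther than a configurable radius
(default 5 a₀, off by default in the drivers) from the auxiliary centre.

**Auxiliary sets.** The nuclear fitting set is generated even-tempered:
exponents from 2√2 to 64 (ratio √2 for the canonical 10-exponent set, i.e.
α_k = 2^((k+2)/2)) shared across s/p/d/f shells — 160 functions per proton;
smaller `et-...` patterns are available for tests. Electronic fitting sets
for energy runs are generated from the orbital basis (`autoaux-tz`/`-qz`):
an even-tempered chain covering the primitive product range, with the qz
level a strict *superset* of tz (geometric midpoints plus one higher angular
momentum). The superset construction is what makes the tz→qz error
non-increase a structural property rather than a lucky outcome. The named
MP2FIT sets ship as counting-only compositions (their per-element spherical
counts are fixed exactly by the cluster-series totals: O 81 / H 30 at the tz
level, O 132 / H 55 at qz) and refuse integral evaluation.

## PNO local MP2 (electronic channel)

Localization is by Jacobi 2×2 sweeps maximizing the Pipek–Mezey Mulliken
functional (or Foster–Boys dipole spread), with canonical ordering seeding
the sweeps — deterministic, and the functional is asserted non-decreasing.
Pairs are screened by their *semicanonical* pair energies (first-order
amplitudes with the diagonal occupied Fock elements and canonical virtuals)
against the four class thresholds; close/weak/distant pairs are kept,
very-distant and below are dropped and their summed estimates reported as a
bound on the neglected energy. Pair densities
`D^ij = (T̃ T† + T̃† T)/(1+δ_ij)` are diagonalized in the **full canonical
virtual space** — deliberately simpler than production PAO→OSV→PNO cascades
with connectivity/radius domain extensions. Consequence: compression
factors and timings of large-scale implementations are not reproduced;
energies in the zero-truncation limit are exact, which is the correctness
property the suite gates on. PNO retention keeps every natural orbital with
occupation ≥ 1e-8 (ties retained) plus enough further PNOs, by descending
occupation, for the truncated semicanonical pair energy to reach 0.997 of
the full one. Amplitudes are solved iteratively in the PNO bases (occupied
Fock non-diagonal after localization; inter-pair couplings projected through
PNO overlaps), Jacobi updates with domain-diagonal denominators, residual
max-norm below 1e-7 (1e-9 where equivalence to canonical is asserted).
Nuclear channels stay canonical — they are a minute fraction of the cost and
the proton orbitals are already local.

## Composite energies and ZPE bookkeeping

`combine` adds NEO-HF reference, an ee correlation energy from any labelled
source, and the MP2-level ep/pp channels; components are tied together by a
geometry hash so an external ee value cannot silently refer to a different
structure. The channels are decoupled at second order, so no cross-terms are
re-evaluated when ee is upgraded. `zpe_partition` converts harmonic
frequencies to a zero-point energy with selected modes excised — when a
quantum proton's stretch is already inside the multicomponent energy it must
not be counted again in a harmonic correction.

## Synthetic inputs and what tests do / do not show

The geometry fixtures (Zundel, Eigen-type clusters, water chains, diatomics)
are idealized textbook internal coordinates (O–H 0.9572 Å, HOH 104.52°,
hydrogen-bond O–O 2.4–2.8 Å), not optimized structures; they exercise the
code paths and size scalings of real clusters without any downloads. The
protonic 4s3p2d2f basis keeps the literature composition (37 spherical
functions per proton, pinned by the cluster counting table) but ships
**synthetic even-tempered exponents** centred on the harmonic-well optimum
for a proton (~12 a₀⁻²) — energies with it are internally consistent but not
comparable to published protonic-basis energies digit by digit. Test
conclusions therefore transfer to real systems for everything structural
(channel formulas, fitting behaviour, truncation limits, counting) and not
for absolute energetics of specific published geometries.

## Problem sizes and numerical choices

Correctness is basis-size independent for every gated property, so the
shipped runs use compact bases chosen as the package's own study
conditions: STO-3G/6-31G electrons, 1–14-function protonic test sets
(the full 37-function set is the production default), water chains up to
n = 4 (20 electron pairs) and the Zundel cation with all five protons
quantum. Exact four-index tensors are size-guarded (8e7 elements) and
refused beyond that with an estimate. Degenerate denominators abort rather
than regularize; PNO retention ties are kept; eigenvalue filtering of
singular metrics cuts at 1e-10 of the largest eigenvalue.

## Known limitations

Open-shell electrons, quantum nuclei other than protons, ghost atoms,
periodic systems and analytic gradients are out of scope. Intrinsic bond
orbitals are not offered as a localizer (Pipek–Mezey and Foster–Boys are).
The SCF does not relocate nuclear basis centres; no F12 or coupled-cluster
electronic solver is included (the composite layer consumes such energies as
external inputs). All integrals are held in memory — appropriate for the
desk-scale systems the package targets.
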
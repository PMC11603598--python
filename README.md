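# neoqc

Multicomponent quantum chemistry for nuclear quantum effects: a
nuclear-electronic orbital (NEO) Hartree–Fock and Møller–Plesset stack in
which selected protons are quantum particles with their own orbital
expansion, not clamped point charges.

**Who it is for.** Anyone studying systems where proton delocalization,
zero-point motion or tunnelling matters — strong hydrogen bonds, protonated
water clusters, proton-coupled processes — and who wants correlated
multicomponent energies without the cost of canonical formulations:
density-fitted integrals throughout, and a pair-natural-orbital (PNO) local
treatment of the dominant electronic correlation channel.

## The model

The NEO-HF reference treats `N_e` electrons (closed shell, doubly occupied
spatial orbitals) and `N_p` quantum protons (identical fermions in one
high-spin channel, singly occupied orbitals) in a single variational wave
function. Electrons and protons couple through attractive mean-field Coulomb
terms; classical nuclei enter as point charges; the proton kinetic energy
carries 1/m_p (m_p = 1836.15267343 m_e).

Second-order perturbation theory on this reference decouples into three
channels (primed indices are nuclear):

    E_ee = Σ_ijab (ia|jb)[2(ia|jb) − (ib|ja)] / (ε_i + ε_j − ε_a − ε_b)
    E_pp = ¼ Σ_i'j'a'b' [(i'a'|j'b') − (i'b'|j'a')]² / (ε_i' + ε_j' − ε_a' − ε_b')
    E_ep = 2 Σ_iai'a' |(ia|i'a')|² / (ε_i + ε_i' − ε_a − ε_a')

Every prefactor is pinned by a brute-force Rayleigh–Schrödinger
sum-over-states oracle (`rspt2_oracle`) that enumerates doubly excited
determinant products explicitly — the two routes agree to ~1e-16 hartree.

Density fitting expands orbital-product densities in an auxiliary Gaussian
set with the robust Coulomb-metric fit, `K ≈ Eᵀ J⁻¹ E`. The ee/pp blocks use
a *unified* electronic+nuclear auxiliary set sharing one metric; the mixed ep
block is fitted in the nuclear auxiliary set alone (an even-tempered
10s10p10d10f set, exponents 2√2 … 64, ratio √2), which is markedly more
accurate for the compact proton densities. `NEO-PNO-LMP2` localizes the
occupied electronic orbitals (Pipek–Mezey/Foster–Boys), screens pairs by
semicanonical energy estimates against close/weak/distant/very-distant
thresholds (1e-4/1e-5/1e-6/1e-7 E_h), and truncates each pair's virtual
space by PNO occupation number (1e-8) and recovered-energy fraction (0.997).
With all thresholds at zero it reproduces the canonical DF result exactly.
A composite assembler, NEO(MP2)-X, swaps the ee channel for an externally
computed higher-level energy while keeping ep/pp at MP2 level.

The Gaussian integral engine (McMurchie–Davidson: overlap, kinetic,
point-charge, dipole, and 2-/3-/4-centre Coulomb integrals over spherical
shells of arbitrary angular momentum) is part of the package.

## Worked example

```python
from neoqc import generate_fixture, run_neo_scf, neo_mp2

model = generate_fixture("h2-twoproton").with_basis(
    electronic="sto-3g", nuclear="prot-sp")
state = run_neo_scf(model)          # interleaved electronic/nuclear SCF, DIIS
result = neo_mp2(state)             # channel-resolved correlation
print(state.energy, result.E_ee, result.E_ep, result.E_pp)
```

prints (see `examples/02_neo_mp2_channels.py` for the full script):

```
NEO-HF reference:  -0.8377639863 hartree
E_ee: -0.011582005259  (sum-over-states -0.011582005259, dev 2.9e-17)
E_ep: -0.000112880851  (sum-over-states -0.000112880851, dev 4.1e-20)
E_pp: -0.000055412002  (sum-over-states -0.000055412002, dev 1.4e-18)
```

The reference energy is the mean-field energy of two electrons plus two
quantum protons (no classical nuclei remain in this system); the three
negative numbers are the channel correlation energies, with proton–proton
correlation orders of magnitude below electron–proton, as expected for
well-separated proton sites. The `examples/` directory holds one short
narrative script per capability: NEO-HF vs clamped RHF, the channel oracle,
DF accuracy vs fitting-set level, the PNO pipeline with pair classes and
domain sizes, and the counting/composite helpers. A thin CLI (`neoqc run`,
`neoqc compare`, `neoqc composite`) wraps the same drivers for flat
key=value config files.

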
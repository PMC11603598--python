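"""NEO-HF on H2 with one quantum proton.

Treating one of the two protons as a quantum particle (with its own orbital
basis) raises the mean-field energy relative to the clamped-nucleus RHF
value: the difference is the zero-point motion of that proton captured
variationally, plus orbital relaxation.
"""

from dataclasses import replace

from neoqc import generate_fixture, run_neo_scf
from neoqc.system import AtomSpec

model = generate_fixture("h2-oneproton").with_basis(electronic="sto-3g",
                                                    nuclear="pb4-f2")
clamped = replace(model, atoms=tuple(
    AtomSpec(a.element, a.position, False) for a in model.atoms))

st_neo = run_neo_scf(model)
st_rhf = run_neo_scf(clamped)

print(f"RHF (both protons clamped):   {st_rhf.energy:.8f} hartree")
print(f"NEO-HF (one quantum proton):  {st_neo.energy:.8f} hartree")
print(f"difference:                   {st_neo.energy - st_rhf.energy:.8f} hartree")
print("The positive difference is the variationally captured zero-point")
print("motion of the quantum proton (about half an H2 stretch quantum).")
print(f"lowest nuclear orbital energy: {st_neo.eps_p[0]:.6f} hartree")
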
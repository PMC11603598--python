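"""System-size bookkeeping and the NEO(MP2)-X composite assembly.

Counting uses only composition and named basis definitions (cc-pVTZ
electrons, the 37-function 4s3p2d2f protonic set, the even-tempered
10s10p10d10f nuclear fitting set, MP2FIT electronic fitting sets), so the
protonated-water-cluster table is exact.  The composite assembler swaps the
ee correlation for an externally computed value while keeping ep/pp at the
MP2 level, and the ZPE helper removes an X-H stretch already contained in
the multicomponent energy.
"""

from neoqc import (CompositeSpec, combine, count_functions, count_occupied,
                   generate_fixture, zpe_partition)

print("cluster   electronic  nuclear  nuc-fit  unified-tz  unified-qz  occ")
for tag, name in (("H5O2+", "zundel"), ("H9O4+", "eigen"),
                  ("H11O5+", "h11o5"), ("H13O6+", "h13o6")):
    m = generate_fixture(name)
    row = (count_functions(m, "electronic"), count_functions(m, "nuclear"),
           count_functions(m, "nuclear-aux"), count_functions(m, "unified-aux"),
           count_functions(m.with_basis(aux_electronic="cc-pvqz-mp2fit"),
                           "unified-aux"))
    print(f"{tag:9s} {row[0]:10d} {row[1]:8d} {row[2]:8d} {row[3]:11d} "
          f"{row[4]:11d}  {count_occupied(m)}")

spec = CompositeSpec(reference_energy=-76.0520, ee_energy=-0.2710,
                     ee_source="PNO-LCCSD(T)-F12", ep_energy=-0.0031,
                     pp_energy=-2.0e-6)
total, prov = combine(spec)
print(f"\n{prov['label']}: E = {total:.6f} hartree")

zpe_full = zpe_partition([3750.0, 3650.0, 1590.0])
zpe_cut = zpe_partition([3750.0, 3650.0, 1590.0], removed_modes=[0])
print(f"harmonic ZPE: {zpe_full:.6f} hartree; after removing the quantum")
print(f"O-H stretch (double counting): {zpe_cut:.6f} hartree")
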
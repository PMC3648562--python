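"""Test whether a network admits exact time-integrals, and inspect why.

Builds the complex-formation network (immobile receptor R + diffusible
ligand L -> immobile complex C), runs the Species-Reaction graph test and
prints the species/reaction partition and the block-triangular
stoichiometric decomposition.
"""

import rdintegral as rd

net = rd.make_complexform()
cert = rd.check_conditions(net)

print("network:", ", ".join(net.species_names), "/",
      ", ".join(r.name for r in net.reactions))
print("passes class conditions:", cert.passes)
print("c1 (react only nonlinearly, must be immobile):",
      [net.species_names[i] for i in cert.c1_indices])
print("c2 (time-integrals computable):",
      [net.species_names[i] for i in cert.c2_indices])
for key, block in cert.blocks.items():
    print(f"{key} =", block.tolist())
print("w =", cert.affine_params["w"].tolist(),
      " W =", cert.affine_params["W"].tolist())

# a broken variant: degrade the complex linearly and the class is lost
broken = rd.example_networks()["complexform_complex_degradation"]
verdict = rd.check_conditions(broken.net)
print("\nwith linear complex degradation:", verdict.passes)
for reason in verdict.failures:
    print("  -", reason)
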
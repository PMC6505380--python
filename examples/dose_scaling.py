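"""Body-surface-area dose translation from mouse to human.

Converts two mouse inhibitor doses to their human equivalents with the
standard Km surface-area factors (mouse 3, adult human 37, 70 kg reference).
"""

from ddipk import human_equivalent_dose, total_human_dose

for drug, dose in [("quinidine", 30.0), ("ketoconazole", 35.0)]:
    hed = human_equivalent_dose(dose, "mouse")
    rounded, unrounded = total_human_dose(dose, "mouse", body_weight=70.0, round_to_mg=10.0)
    print(f"{drug:13s} {dose:4.0f} mg/kg mouse -> {hed:.2f} mg/kg human "
          f"-> {unrounded:.1f} mg/70 kg (~{rounded:.0f} mg)")

print()
print("The rounded totals are the practical human doses matching the animal")
print("exposure on a surface-area basis (170 and 200 mg respectively).")
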
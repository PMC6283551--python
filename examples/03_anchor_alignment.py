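"""Anchor selected nonamers into a P5-P4' frame and build a positional profile.

Peptides with a single P1-candidate residue are anchored first; peptides with
several candidates are placed at the offset that best fits the emerging
profile, iterating to a stable assignment.
"""

from cleavemap import Peptide, align_unambiguous, resolve_and_iterate

# a small hand-made pool: F/Y/W are the P1 candidates (chymase-like)
peptides = [
    Peptide("ADGFSDEAK", 3),   # one F: unambiguous anchor
    Peptide("TSVYEDALG"),      # one Y: unambiguous anchor
    Peptide("GAGWTEKSA"),      # one W: unambiguous anchor
    Peptide("AFATYDESA"),      # F and Y: ambiguous, fitted to the profile
    Peptide("LYAATFDDG"),      # Y and F: ambiguous
    Peptide("AAAGSTKLM"),      # no candidate: unalignable
]

unamb, amb, unalign = align_unambiguous(peptides, "FYW")
print(f"{len(unamb)} unambiguous anchors, {len(amb)} ambiguous, "
      f"{len(unalign)} unalignable")

result = resolve_and_iterate(unamb, amb, "FYW")
print(f"converged in {result.n_iterations} passes\n")
print("P5-P4' alignment (lowercase = arm residue, '-' = outside construct):")
for ap in result.aligned:
    row = "".join(
        "-" if fr.residue is None
        else fr.residue.lower() if fr.arm_derived
        else fr.residue
        for fr in ap.frame_residues
    )
    print(f"  {row}  x{ap.peptide.multiplicity}  (P1 at insert pos {ap.p1_offset})")

print("\nprofile P1 row (probability per residue, arm positions masked):")
p1 = result.profile.to_dataframe().loc["P1"]
print("  " + "  ".join(f"{aa}:{p:.2f}" for aa, p in p1.items() if p > 0.05))
print("\nEach ambiguous peptide sits where its context best matches the "
      "consensus built from the unambiguous anchors.")
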
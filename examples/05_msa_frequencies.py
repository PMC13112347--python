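"""Position-wise residue frequencies from a multiple sequence alignment.

Maps ungapped reference positions through the alignment and counts
residues per column (gaps excluded), the ingredient of conservation
logos for interface positions.
"""

import zernipep as zp

ALIGNMENT = """\
>ref
APK-LMIY
>seq2
APKQLMIY
>seq3
APRQLL-Y
>seq4
-PKQLMIY
"""

freqs = zp.msa_position_frequencies(ALIGNMENT, positions=[1, 3, 5], reference_id="ref")
for pos, col in freqs.items():
    pretty = ", ".join(f"{res}: {f:.2f}" for res, f in sorted(col.items()))
    print(f"reference position {pos}: {pretty}")
# Frequencies near 1.0 mark conserved sites; mixtures mark variable ones.
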
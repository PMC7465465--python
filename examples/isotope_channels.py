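"""Chlorine isotope pattern and SIM channel selection for dicamba.

Dicamba carries two chlorines, so its [M-H]- ion at m/z 219 and its
decarboxylation fragment at m/z 175 each come with an M+2 isotopologue
(~"3:2" M:M+2). The quantification channels are the 35Cl-only ions; the
D3-labeled internal standard shifts every channel by +3 Da.
"""

from sidquant import D3_DICAMBA, DICAMBA, chlorine_pattern

pattern = chlorine_pattern(2)
print("Cl2 isotopologue fractions:")
for offset, p in pattern.fractions:
    print(f"  M+{offset}: {p:.5f}")
print(f"M:M+2 ratio = {pattern.m_mplus2_ratio:.4f}  (the '3:2' signature)")

print(f"\nanalyte quant channels:  {sorted(DICAMBA.quant_channels)}")
print(f"analyte confirm channels: {sorted(DICAMBA.confirm_channels)}")
print(f"IS quant channels:       {sorted(D3_DICAMBA.quant_channels)}")
# The M:M+2 ratio near 1.56 identifies a di-chlorinated compound; the IS
# channels are the analyte channels shifted by the +3 Da deuterium label.
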
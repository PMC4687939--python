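"""Fatty-acid composition indices from published group means.

Uses the published Biceps femoris intramuscular fatty-acid composition of
newborn purebred Iberian (IB) and Iberian x Duroc (IBxDU) piglets and
computes the class sums (SFA/MUFA/PUFA), the omega-family sums, the
unsaturation index UI = sum of k x (% fatty acids with k double bonds),
and the headline ratios.
"""

from rifpipe import summary_indices
from rifpipe.reference_data import piglet_fatty_acid_means

for group in ("IBxDU", "IB"):
    idx = summary_indices(piglet_fatty_acid_means(group))
    print(f"\n{group}:")
    print(f"  sum SFA   {idx['sum_sfa']:6.2f}   (saturated)")
    print(f"  sum MUFA  {idx['sum_mufa']:6.2f}   (monounsaturated)")
    print(f"  sum PUFA  {idx['sum_pufa']:6.2f}   (polyunsaturated)")
    print(f"  UI        {idx['ui']:6.2f}   (double-bond-weighted)")
    print(f"  MUFA/SFA  {idx['mufa_sfa_ratio']:6.2f}")
# Higher MUFA/SFA in the purebred line reflects its characteristic
# oleic-acid-rich intramuscular fat.
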
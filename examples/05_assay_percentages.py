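"""Radical-scavenging percentages from absorbance readings.

Applies the shared DPPH / hydroxyl formula (A0 - A1)/A0 * 100 to a small
table of mock absorbance readings.
"""

import aopgen as ag

a0 = 0.8  # negative-control absorbance
print("sample  A1     scavenging %")
for sample, a1 in [("GP1", 0.20), ("GP2", 0.40), ("GP5", 0.55), ("blank", 0.80)]:
    pct = ag.scavenging_percent(a0=a0, a1=a1)
    print(f"{sample:<7} {a1:.2f}   {pct:6.1f}")
# 100% means the sample quenched the radical signal completely; 0% means the
# absorbance did not drop relative to the control.
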
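"""Classify organ tropism from luminescence readouts.

A treatment is spleen-tropic when its spleen:liver luminescence ratio
exceeds the ratio measured in PBS-treated control animals, and
liver-tropic otherwise.
"""

from bcscreen import OrganSignal, classify_tropism

baseline = 0.35  # spleen:liver ratio in PBS-treated mice

candidates = {
    "LNP-A": OrganSignal(spleen_signal=4.2e6, liver_signal=9.0e5,
                         baseline_ratio=baseline),
    "LNP-B": OrganSignal(spleen_signal=8.0e5, liver_signal=6.5e6,
                         baseline_ratio=baseline),
    "LNP-C": OrganSignal(spleen_signal=3.5e5, liver_signal=1.0e6,
                         baseline_ratio=baseline),
}

for name, sig in candidates.items():
    ratio = sig.spleen_signal / sig.liver_signal
    print(f"{name}: spleen:liver = {ratio:.3f} vs baseline {baseline} "
          f"-> {classify_tropism(sig)}")
# A ratio above baseline indicates preferential splenic transfection;
# LNP-C sits exactly at the decision rule's liver-tropic side.
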
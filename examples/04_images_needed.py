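"""Derive the minimum image budget from the log accuracy model.

Uses the published regression coefficients of both strategies
(accuracy = a*ln(images) + b) and solves for the smallest whole number
of images predicted to reach the 95% accuracy limit.
"""

from diatomtest import images_needed, predict_accuracy
from diatomtest.datasets import SCATTER_CURVE, TRANSECT_CURVE

for curve in (TRANSECT_CURVE, SCATTER_CURVE):
    n = images_needed(curve, 95.0)
    print(f"{curve.strategy}: accuracy = {curve.a}*ln(n) + {curve.b}")
    print(f"  -> {n} images reach 95% (predicted "
          f"{predict_accuracy(curve, n):.2f}%, at {n - 1} images only "
          f"{predict_accuracy(curve, n - 1):.2f}%)")
# 78 transect images vs 50 scatter images: the scatter strategy reaches
# the reliability target with roughly one third fewer SEM fields.
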
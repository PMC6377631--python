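"""Calibrated Beam-Film parameter presets for the study-like conditions.

L, T2prob and M carry the fitted values for each sex and background; Smax
was calibrated once (bisection at 40k bivalents) so the designated class I
mean per bivalent matches the corresponding fitted class I frequency, and
T2prob for the B73xMo17 sets follows the closed form
``class II mean = T2prob * (N - designated)``.  N=16, E=1, B=1, Y=1, A=1
throughout (the precursor-array defaults of the full-chromosome fits).

Realized per-bivalent means at these presets (40k-bivalent check):

==============  ====  ======  ===  ==========  ======  ========
set             L     T2prob  M    designated  mature  class II
==============  ====  ======  ===  ==========  ======  ========
zs_female       0.45  0.022   1.0  1.96        1.96    0.31
zs_male         0.23  0.062   1.0  3.10        3.10    0.80
bm_female       0.40  0.0099  0.9  1.91        1.72    0.14
bm_male         0.25  0.0159  0.7  2.19        1.54    0.22
==============  ====  ======  ===  ==========  ======  ========

zs = Zheng58 x SK gametophyte populations; bm = B73 x Mo17 reciprocal
crosses (the two CMI backgrounds).
"""

from .bf_sim import BFParams

__all__ = ["ZS_FEMALE", "ZS_MALE", "BM_FEMALE", "BM_MALE", "BIVALENTS_PER_MEIOSIS"]

#: maize has 10 bivalents per meiosis
BIVALENTS_PER_MEIOSIS = 10

ZS_FEMALE = BFParams(N=16, E=1, B=1, Y=1, A=1, Smax=2.578, L=0.45, M=1.0,
                     T2prob=0.022)
ZS_MALE = BFParams(N=16, E=1, B=1, Y=1, A=1, Smax=2.665, L=0.23, M=1.0,
                   T2prob=0.062)
BM_FEMALE = BFParams(N=16, E=1, B=1, Y=1, A=1, Smax=1.895, L=0.40, M=0.9,
                     T2prob=0.0099)
BM_MALE = BFParams(N=16, E=1, B=1, Y=1, A=1, Smax=1.482, L=0.25, M=0.7,
                   T2prob=0.0159)
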
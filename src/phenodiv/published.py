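"""Published summary tables of the 113-accession moso bamboo survey.

The raw accession × trait matrix of the nationwide survey was never
deposited, but several of its summary tables were printed in full.  Those
printed numbers are reproduced here so that the desk-scale reductions the
survey reports — the panel-mean coefficient of variation, the principal
component retention and weights, and the composite-score (D-value)
extremes — can be recomputed from first principles and compared against
the same pipeline run on synthetic panels.

Values are stored exactly as printed (percent CVs to 2 dp, D-values to
3 dp); nothing here is produced by this package's own computation.
"""

from __future__ import annotations

#: Printed coefficient of variation (%) per trait, in catalog order.
#: Note these were rounded from the survey's raw data, so a handful differ
#: in the last digit from sd/mean recomputed off the rounded moments.
TABLE_CV_PERCENT: dict[str, float] = {
    "DBH": 11.97, "DG": 12.84, "TG": 11.84, "H": 9.84, "TNN": 7.51,
    "HuB": 18.56, "NNuB": 11.65, "LN": 7.53, "PC": 11.06, "WC": 26.14,
    "BLr": 33.33, "WBL": 26.90, "WB": 29.65, "WL": 33.96, "W": 24.23,
    "Cwr": 21.84, "Bmc": 21.15, "Lmc": 36.57, "TABP": 12.03, "TABH": 12.68,
    "CD": 12.89, "WCr": 10.78, "LT": 11.13, "LA": 14.24, "LL": 7.49,
    "LW": 7.81, "LAr": 5.87, "SLA": 14.69,
}

#: Eigenvalues of the 28-trait correlation matrix for the eight retained
#: principal components (eigenvalue > 1 rule).
PC_EIGENVALUES: tuple[float, ...] = (
    9.241, 3.985, 2.335, 1.967, 1.830, 1.290, 1.185, 1.026,
)

#: Contribution rates (%) of the eight retained components.
PC_CONTRIBUTION_PERCENT: tuple[float, ...] = (
    33.002, 14.231, 8.338, 7.026, 6.536, 4.608, 4.232, 3.663,
)

#: Published composite D-scores: accession name -> (D, published rank).
D_SCORES: dict[str, tuple[float, int]] = {
    "Huangshan 1": (0.550, 62), "Huangshan 2": (0.556, 61),
    "Guangde 1": (0.695, 8), "Guangde 2": (0.466, 97),
    "Ningguo 1": (0.599, 44), "Ningguo 2": (0.584, 51),
    "Huoshan 1": (0.785, 2), "Huoshan 2": (0.634, 28),
    "Dehua 1": (0.644, 23), "Dehua 2": (0.689, 10),
    "Yongan 1": (0.427, 105), "Yongan 2": (0.612, 39),
    "Wuyi 1": (0.803, 1), "Wuyi 2": (0.703, 5),
    "Jianou 1": (0.716, 3), "Jianou 2": (0.668, 14),
    "Jiaocheng 1": (0.664, 17), "Jiaocheng 2": (0.647, 21),
    "Nanzhao 1": (0.405, 108), "Shihe 1": (0.493, 84),
    "Xinxian 1": (0.614, 38), "Xinxian 2": (0.487, 90),
    "Yiliang 1": (0.533, 68), "Yiliang 2": (0.684, 13),
    "Changning 1": (0.535, 67), "Changning 2": (0.638, 25),
    "Muchuan 1": (0.631, 29), "Muchuan 2": (0.617, 35),
    "Tianquan 1": (0.624, 32), "Tianquan 2": (0.491, 87),
    "Zizhong 1": (0.643, 24), "Pingle 1": (0.375, 111),
    "Pingle 2": (0.317, 113), "Xing'an 1": (0.517, 74),
    "Xing'an 2": (0.460, 98), "Sanjiang 1": (0.540, 66),
    "Sanjiang 2": (0.528, 70), "Rong'an 1": (0.492, 86),
    "Rong'an 2": (0.647, 21), "Pingjiang 1": (0.608, 40),
    "Pingjiang 2": (0.441, 103), "Taojiang 1": (0.629, 31),
    "Taojiang 2": (0.544, 65), "Taoyuan 1": (0.548, 63),
    "Taoyuan 2": (0.607, 41), "Xiangtan 1": (0.516, 76),
    "Xiangtan 2": (0.474, 93), "Hengyang 1": (0.526, 71),
    "Hengyang 2": (0.506, 80), "Suining 1": (0.638, 25),
    "Suining 2": (0.605, 42), "Shuangpai 1": (0.557, 59),
    "Shuangpai 2": (0.592, 49), "Yanling 1": (0.576, 54),
    "Yanling 2": (0.565, 57), "Wanli 1": (0.451, 99),
    "Wanli 2": (0.649, 19), "Jiujiang 1": (0.445, 100),
    "Jiujiang 2": (0.692, 9), "Yifeng 1": (0.557, 59),
    "Yifeng 2": (0.500, 82), "Anfu 1": (0.593, 48),
    "Anfu 2": (0.638, 25), "Shangrao 1": (0.510, 79),
    "Shangrao 2": (0.570, 55), "Yihuang 1": (0.531, 69),
    "Yihuang 2": (0.515, 77), "Ruijin 1": (0.504, 81),
    "Ruijin 2": (0.427, 105), "Chongyi 1": (0.594, 47),
    "Chongyi 2": (0.569, 56), "Fenghua 1": (0.667, 15),
    "Fenghua 2": (0.493, 84), "Huangyan 1": (0.686, 12),
    "Huangyan 2": (0.499, 83), "Jinyun 1": (0.648, 20),
    "Jinyun 2": (0.621, 34), "Longyou 1": (0.522, 73),
    "Longyou 2": (0.517, 74), "Anji 1": (0.583, 52),
    "Anji 2": (0.467, 96), "Zhuji 1": (0.623, 33),
    "Zhuji 2": (0.478, 91), "Chun'an 1": (0.616, 36),
    "Chun'an 2": (0.563, 58), "Jurong 1": (0.445, 100),
    "Yixing 1": (0.426, 107), "Yixing 2": (0.489, 88),
    "Liyang 1": (0.583, 52), "Chibi 1": (0.548, 63),
    "Chibi 2": (0.599, 44), "Yangxin 1": (0.405, 108),
    "Yangxin 2": (0.591, 50), "Huangmei 1": (0.701, 6),
    "Lutian 1": (0.665, 16), "Jingshan 1": (0.472, 94),
    "Shishou 1": (0.489, 88), "Enshi 1": (0.699, 7),
    "Enshi 2": (0.445, 100), "Yidu 1": (0.596, 46),
    "Nanzhang 1": (0.382, 110), "Zhushan 1": (0.374, 112),
    "Changshou 1": (0.476, 92), "Changshou 2": (0.526, 71),
    "Liangping 1": (0.659, 18), "Fengdu 1": (0.429, 104),
    "Fengdu 2": (0.708, 4), "Xiushan 1": (0.631, 29),
    "Xiushan 2": (0.689, 10), "Jiangjin 1": (0.514, 78),
    "Jiangjin 2": (0.468, 95), "Chishui 1": (0.615, 37),
    "Chishui 2": (0.600, 43),
}

#: Published group-mean D-values of the four cluster groups (I..IV).
GROUP_MEAN_D: tuple[float, ...] = (0.62, 0.47, 0.56, 0.50)
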
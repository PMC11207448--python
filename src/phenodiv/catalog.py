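"""Trait catalog for the Chinese moso bamboo (*Phyllostachys edulis*) germplasm panel.

The 28 phenotypic traits span growth (diameter at breast height, height,
biomass fractions), culm form (taper, node counts, wall thickness, cavity
diameter) and leaf morphology (area, shape, specific leaf area).  Each
:class:`TraitDefinition` carries the published panel-level moments
(minimum, maximum, mean, standard deviation) of the 113-accession
nationwide survey, which parameterize the synthetic-panel generator and
anchor the reporting layer.

Three traits are ratios derived from primary measurements rather than
direct readings: the wall-to-cavity ratio (WCr), the branch-to-leaf ratio
(BLr) and the specific leaf area (SLA).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class TraitDefinition:
    """One phenotypic trait: identity, units and panel-level moments."""

    abbreviation: str
    full_name: str
    units: str
    mean: float
    sd: float
    min_bound: float
    max_bound: float
    derived: bool = False

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"{self.abbreviation}: sd must be >= 0, got {self.sd}")
        if not (self.min_bound <= self.mean <= self.max_bound):
            raise ValueError(
                f"{self.abbreviation}: mean {self.mean} outside "
                f"[{self.min_bound}, {self.max_bound}]"
            )


def _t(abbr, name, units, lo, hi, mean, sd, derived=False):
    return TraitDefinition(
        abbreviation=abbr,
        full_name=name,
        units=units,
        mean=mean,
        sd=sd,
        min_bound=lo,
        max_bound=hi,
        derived=derived,
    )


#: The 28-trait catalog in canonical column order.
DEFAULT_CATALOG: tuple[TraitDefinition, ...] = (
    _t("DBH", "Diameter at breast height", "cm", 6.45, 12.73, 10.28, 1.23),
    _t("DG", "Diameter at ground", "cm", 7.13, 15.27, 11.82, 1.52),
    _t("TG", "Taper grade", "cm·m⁻¹", 0.52, 1.14, 0.75, 0.09),
    _t("H", "Height", "m", 12.08, 19.67, 15.70, 1.54),
    _t("TNN", "Total number of nodes", "node", 50.0, 72.0, 63.27, 4.75),
    _t("HuB", "Height under branch", "m", 4.36, 10.87, 7.21, 1.34),
    _t("NNuB", "Number of nodes under branch", "node", 18.0, 35.0, 27.22, 3.17),
    _t("LN", "Length of node at breast diameter", "cm", 20.83, 30.00, 24.35, 1.83),
    _t("PC", "Plant crown", "m", 1.58, 3.02, 2.27, 0.25),
    _t("WC", "Weight of culms", "kg", 9.73, 44.45, 26.44, 6.91),
    _t("BLr", "Branch-to-leaf ratio", "g·g⁻¹", 0.72, 3.56, 1.72, 0.57, derived=True),
    _t("WBL", "Weight of branches and leaves", "kg", 2.36, 11.03, 6.49, 1.75),
    _t("WB", "Weight of branches", "kg", 1.65, 6.90, 3.85, 1.14),
    _t("WL", "Weight of leaves", "kg", 0.53, 4.99, 2.64, 0.90),
    _t("W", "Total weight", "kg", 13.62, 52.82, 32.91, 7.97),
    _t("Cwr", "Culm moisture content", "g·g⁻¹", 0.51, 1.63, 0.88, 0.19),
    _t("Bmc", "Branch moisture content", "g·g⁻¹", 0.42, 1.66, 0.61, 0.13),
    _t("Lmc", "Leaf moisture content", "g·g⁻¹", 0.49, 4.54, 1.10, 0.40),
    _t("TABP", "Thickness at base of pole", "mm", 9.85, 21.71, 16.54, 1.99),
    _t("TABH", "Thickness at breast height", "mm", 6.66, 16.04, 10.22, 1.30),
    _t("CD", "Cavity diameter", "mm", 49.21, 104.32, 80.48, 10.38),
    _t("WCr", "Wall-to-cavity ratio", "mm·mm⁻¹", 0.20, 0.39, 0.26, 0.03, derived=True),
    _t("LT", "Leaf thickness", "mm", 0.09, 0.16, 0.13, 0.01),
    _t("LA", "Leaf area", "cm²", 6.80, 15.14, 10.45, 1.49),
    _t("LL", "Leaf length", "cm", 7.29, 12.08, 10.05, 0.75),
    _t("LW", "Leaf width", "cm", 1.21, 1.81, 1.48, 0.12),
    _t("LAr", "Leaf aspect ratio", "cm·cm⁻¹", 5.24, 7.91, 6.82, 0.40),
    _t("SLA", "Specific leaf area", "cm²·g⁻¹", 129.26, 271.07, 182.59, 26.83, derived=True),
)

#: Canonical trait order, used for CSV schemas and tie-breaking.
TRAIT_ORDER: tuple[str, ...] = tuple(t.abbreviation for t in DEFAULT_CATALOG)

CATALOG_BY_ABBREVIATION: dict[str, TraitDefinition] = {
    t.abbreviation: t for t in DEFAULT_CATALOG
}

#: The seven key traits selected by the PCA screening of the published panel.
PUBLISHED_KEY_TRAITS: tuple[str, ...] = ("DBH", "LA", "WL", "BLr", "Lmc", "WCr", "LN")

#: Cluster-group sizes of the published four-group partition (I..IV).
GROUP_SIZES: tuple[int, ...] = (54, 26, 25, 8)

#: Group labels in decreasing-size order.
GROUP_LABELS: tuple[str, ...] = ("I", "II", "III", "IV")

# Published per-group trait means of the four-group partition.  In the
# original table the wall-thickness (TABH) and cavity-diameter (CD) rows
# are transposed — the values printed against TABH are on the 70–87 mm
# cavity scale while those against CD sit on the ~10 mm wall scale — so
# they are stored here under the trait they actually describe.
GROUP_TRAIT_MEANS: dict[str, tuple[float, float, float, float]] = {
    "DBH": (11.05, 8.88, 10.28, 9.70),
    "DG": (12.77, 10.10, 11.79, 11.03),
    "TG": (0.76, 0.70, 0.78, 0.76),
    "H": (16.66, 14.37, 15.30, 14.81),
    "TNN": (65.37, 58.92, 64.12, 60.63),
    "HuB": (7.98, 6.34, 6.61, 6.68),
    "NNuB": (29.17, 24.31, 26.40, 26.13),
    "LN": (24.32, 25.05, 23.72, 24.28),
    "PC": (2.31, 2.20, 2.25, 2.22),
    "WC": (31.07, 19.56, 24.91, 22.24),
    "BLr": (1.81, 1.51, 1.70, 1.86),
    "WBL": (6.84, 5.27, 7.20, 5.93),
    "WB": (4.19, 2.93, 4.19, 3.56),
    "WL": (2.66, 2.34, 3.01, 2.37),
    "W": (37.88, 24.83, 32.11, 28.17),
    "Cwr": (0.83, 0.88, 0.96, 0.93),
    "Bmc": (0.58, 0.60, 0.67, 0.71),
    "Lmc": (1.08, 1.06, 1.13, 1.31),
    "TABP": (17.37, 15.31, 16.21, 15.88),
    "TABH": (10.77, 9.14, 10.34, 9.72),
    "CD": (86.69, 69.17, 80.23, 76.18),
    "WCr": (0.25, 0.27, 0.26, 0.26),
    "LT": (0.13, 0.13, 0.12, 0.13),
    "LA": (10.66, 10.61, 10.26, 9.15),
    "LL": (10.20, 10.00, 10.06, 9.07),
    "LW": (1.49, 1.50, 1.44, 1.44),
    "LAr": (6.87, 6.69, 7.01, 6.35),
    "SLA": (166.91, 176.21, 202.19, 247.93),
}

#: Provinces represented in the nationwide survey (used for synthetic labels).
PROVINCES: tuple[str, ...] = (
    "Anhui", "Fujian", "Henan", "Yunnan", "Sichuan", "Guangxi", "Hunan",
    "Jiangxi", "Zhejiang", "Jiangsu", "Hubei", "Chongqing", "Guizhou", "Shaanxi",
)
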
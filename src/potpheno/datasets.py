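"""Bundled reference tables from a published six-genotype rice
salinity pot screen (three doubled-haploid lines, the Ciherang mega
variety, and the IRRI tolerant/sensitive checks Pokkali and IR29).

These small tables let the arithmetic of the screening chain be
exercised and demonstrated without images or raw trial data: the
ANOVA p-value column drives the stress-significance filter, the STI
matrix feeds the PCA grouping stage, and the ion contents feed the
relative-change and K+/Na+ summaries.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "load_anova_pvalues",
    "load_sti_matrix",
    "load_relative_changes",
    "load_ion_contents",
]

# per-trait p-values of the stress, genotype and genotype x stress
# sources, plus the CV (%) of the log-transformed analysis
_ANOVA = [
    # trait, p_stress, p_genotype, p_gxs, cv_trans
    ("convex_area",        0.002, 0.513, 0.967,   8.16),
    ("green_area",         0.007, 0.707, 0.997,  23.59),
    ("saturation_area",    0.000, 0.975, 0.576,  12.69),
    ("ratio_sat_conv",     0.000, 0.903, 0.449,  36.66),
    ("ratio_green_conv",   0.638, 0.369, 0.513, 229.55),
    ("ratio_green_sat",    0.173, 0.635, 0.581, 137.65),
    ("perimeter",          0.015, 0.713, 0.994,  16.65),
    ("width",              0.000, 0.401, 0.547,  10.45),
    ("height",             0.109, 0.448, 0.506,   5.79),
    ("major",              0.006, 0.838, 0.628,   9.19),
    ("minor",              0.001, 0.923, 0.854,  26.43),
    ("feret",              0.007, 0.173, 0.411,   4.78),
    ("integrated_density", 0.016, 0.892, 0.909,  12.85),
    ("min_feret",          0.000, 0.587, 0.394,  18.02),
    ("aspect_ratio",       0.030, 0.589, 0.973,  56.35),
    ("roundness",          0.028, 0.591, 0.982,  26.83),
    ("red_index",          0.449, 0.844, 0.709,  20.51),
    ("green_index",        0.562, 0.924, 0.878,  27.17),
    ("blue_index",         0.062, 0.933, 0.279,  15.14),
]

# stress tolerance indices of the eight ANOVA-selected traits
_STI = {
    "genotype":        ["HS4.15.1.70", "HS4.15.2.4", "HS4.45.1.66",
                        "Ciherang", "IR29", "Pokkali"],
    "convex_area":     [0.53, 0.63, 0.43, 0.30, 0.54, 0.99],
    "saturation_area": [0.15, 0.20, 0.19, 0.40, 0.35, 0.34],
    "perimeter":       [0.55, 0.61, 0.32, 0.27, 0.32, 0.43],
    "width":           [0.59, 0.66, 0.75, 0.37, 0.47, 0.78],
    "major":           [0.58, 0.71, 0.70, 0.64, 0.94, 0.87],
    "feret":           [0.84, 0.88, 0.74, 0.57, 0.92, 1.13],
    "min_feret":       [0.56, 0.61, 0.38, 0.35, 0.51, 0.63],
    "roundness":       [0.44, 0.77, 1.37, 0.65, 0.46, 0.59],
}

# relative decrease (%) of pigments and relative increase (%) of proline
_REL = {
    "genotype":    ["HS4.15.1.70", "HS4.15.2.4", "HS4.45.1.66",
                    "Ciherang", "IR29", "Pokkali"],
    "rd_chl_tot":  [26.36, 38.59, 52.37, 50.13, 31.85, 11.50],
    "rd_chl_a":    [26.77, 42.69, 50.90, 52.93, 32.21, 11.60],
    "rd_chl_b":    [25.23, 27.09, 55.71, 42.33, 30.88, 11.24],
    "rd_car":      [15.58, 46.04, 31.01, 37.98, -15.30, 9.99],
    "ri_proline":  [322.50, -9.60, 1726.25, 133.75, 1001.18, 513.45],
}

# K+ contents of the tolerant check under both environments, and the Na+
# content of the moderate line under salt, as printed in the screen's
# ion-balance comparison of three representative genotypes
_IONS = [
    # genotype, environment, na, k
    ("Pokkali", "normal", 0.95, 3.99),
    ("Pokkali", "saline", 1.35, 3.06),
    ("HS4.45.1.66", "normal", 0.16, 3.20),
    ("HS4.45.1.66", "saline", 4.41, 2.10),
    ("IR29", "normal", 1.10, 1.30),
    ("IR29", "saline", 3.10, 1.20),
]


def load_anova_pvalues() -> pd.DataFrame:
    """ANOVA p-values (stress / genotype / GxS) and CV_trans per trait."""
    return pd.DataFrame(
        _ANOVA, columns=["trait", "p_stress", "p_genotype", "p_gxs", "cv_trans"]
    ).set_index("trait")


def load_sti_matrix() -> pd.DataFrame:
    """6 genotypes x 8 traits stress-tolerance-index matrix."""
    return pd.DataFrame(_STI).set_index("genotype")


def load_relative_changes() -> pd.DataFrame:
    """Published relative pigment decreases / proline increase (%)."""
    return pd.DataFrame(_REL).set_index("genotype")


def load_ion_contents() -> pd.DataFrame:
    """Na+/K+ contents of three representative genotypes.

    The Pokkali K+ values (3.99 normal, 3.06 saline) are as published;
    the remaining cells are approximate values read off the published
    bar charts and are intended for demonstration, not reproduction.
    """
    return pd.DataFrame(_IONS, columns=["genotype", "environment", "na", "k"])
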
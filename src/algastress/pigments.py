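"""Spectrophotometric chlorophyll a/b quantification from absorbance triplets.

Chlorophyll is extracted in 80:20 acetone/methanol and quantified from
absorbances at 663, 645 and 750 nm.  The 750 nm reading carries no
chlorophyll signal and serves as a turbidity/baseline correction:

    E663 = A663 - A750,   E645 = A645 - A750

    chl a   (ug/mL) = (12.25 * E663 -  2.55 * E645) / volume_mL
    chl b   (ug/mL) = (20.31 * E645 -  4.91 * E663) / volume_mL
    chl a+b (ug/mL) = (17.76 * E645 +  7.34 * E663) / volume_mL

The total is the exact sum of the a and b equations
(12.25 - 4.91 = 7.34 and 20.31 - 2.55 = 17.76), so ``chl_total ==
chl_a + chl_b`` holds identically; the package computes the total from its
own equation and the identity is asserted property-wise in the tests.

Per-cell content uses the culture-density proxy 1 OD750 ~ 1e7 cells/mL.
"""

from __future__ import annotations

from dataclasses import dataclass

# Extinction-coefficient matrix of the a/b equations, laid out as
# [[dA663 coeff on chl a, dE645 coeff on chl a], [... chl b ...]].
COEF_A_663 = 12.25
COEF_A_645 = -2.55
COEF_B_645 = 20.31
COEF_B_663 = -4.91
COEF_TOT_645 = 17.76
COEF_TOT_663 = 7.34

CELLS_PER_ML_PER_OD750 = 1.0e7


@dataclass(frozen=True)
class ChlorophyllResult:
    """Concentrations derived from one absorbance triplet.

    Attributes
    ----------
    E663, E645 : float
        Baseline-corrected absorbances (A663 - A750, A645 - A750).
    chl_a, chl_b, chl_total : float
        Concentrations in ug/mL of extract.
    negative_flag : bool
        True when any computed concentration is negative.  Negative values
        are reported as-is (clamping would break the additivity identity);
        the flag marks the sample for QC.
    chl_per_cell : float or None
        Chlorophyll content per cell in pg/cell, when an OD750 was supplied.
    cells_per_ml : float or None
        Cell density inferred from OD750.
    """

    E663: float
    E645: float
    chl_a: float
    chl_b: float
    chl_total: float
    negative_flag: bool
    chl_per_cell: float | None = None
    cells_per_ml: float | None = None


def chlorophyll_concentrations(
    a663: float,
    a645: float,
    a750: float,
    volume_ml: float,
    od750: float | None = None,
) -> ChlorophyllResult:
    """Compute chlorophyll a, b and total from an absorbance triplet.

    Parameters
    ----------
    a663, a645, a750 : float
        Raw absorbances at 663, 645 and 750 nm.
    volume_ml : float
        Sample volume in mL; must be positive.
    od750 : float, optional
        Culture OD750 of the sample; when given, per-cell content is
        also computed (see :func:`per_cell_content`).
    """
    if not volume_ml > 0:
        raise ValueError(f"volume_ml must be positive, got {volume_ml}")
    e663 = a663 - a750
    e645 = a645 - a750
    chl_a = (COEF_A_663 * e663 + COEF_A_645 * e645) / volume_ml
    chl_b = (COEF_B_645 * e645 + COEF_B_663 * e663) / volume_ml
    chl_total = (COEF_TOT_645 * e645 + COEF_TOT_663 * e663) / volume_ml
    flag = chl_a < 0 or chl_b < 0 or chl_total < 0
    per_cell = None
    cells = None
    if od750 is not None:
        per_cell = per_cell_content(chl_total, od750)
        cells = od750 * CELLS_PER_ML_PER_OD750
    return ChlorophyllResult(
        E663=e663,
        E645=e645,
        chl_a=chl_a,
        chl_b=chl_b,
        chl_total=chl_total,
        negative_flag=flag,
        chl_per_cell=per_cell,
        cells_per_ml=cells,
    )


def per_cell_content(chl_ug_per_ml: float, od750: float) -> float:
    """Chlorophyll per cell in pg/cell from a bulk concentration and OD750.

    cells/mL = OD750 * 1e7; pg/cell = (ug/mL * 1e6 pg/ug) / (cells/mL).
    """
    if not od750 > 0:
        raise ValueError(f"od750 must be positive, got {od750}")
    cells_per_ml = od750 * CELLS_PER_ML_PER_OD750
    return chl_ug_per_ml * 1.0e6 / cells_per_ml
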
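"""Regional fibre-length heterogeneity: balanced two-way ANOVA.

The pectoralis pars posterior is sampled over a 4 (cranial-caudal
compartment M1-M4) x 2 (superficial/deep) grid with equal numbers of fibres
per cell. For a balanced design the sums of squares decompose exactly:

    SS_total = SS_compartment + SS_depth + SS_interaction + SS_error,

with SS terms computed from cell and marginal means, F = MS_effect /
MS_error, and p-values from the F distribution. Simple main effects test
one factor within a level of the other, by default against the pooled
full-model error term. Post hoc cell comparisons use Bonferroni correction
with an explicit family size. The significance threshold defaults to
alpha = 0.025.

Only balanced designs are accepted: with unequal cell counts the factorial
decomposition is no longer unique (Type I/II/III sums of squares diverge),
and silently picking one would be a modelling decision, not arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
from scipy import stats

from .constants import DEFAULT_CONSTANTS
from .records import FibreSample

__all__ = [
    "two_way_anova",
    "two_way_anova_array",
    "simple_main_effects",
    "pairwise_depth_comparisons",
    "bonferroni",
    "AnovaResult",
]


@dataclass
class AnovaResult:
    """Two-way ANOVA decomposition for a balanced factorial design."""

    factor_a: str  # e.g. "compartment"
    factor_b: str  # e.g. "depth"
    levels_a: Tuple[str, ...]
    levels_b: Tuple[str, ...]
    n_per_cell: int
    ss: Dict[str, float]  # keys: a, b, interaction, error, total
    df: Dict[str, int]
    ms: Dict[str, float]
    f_stats: Dict[str, float]  # keys: a, b, interaction
    p_values: Dict[str, float]
    cell_means: np.ndarray = field(repr=False, default=None)  # shape (a, b)

    def summary(self) -> str:
        """Plain-text ANOVA table."""
        lines = [
            f"{'Source':<22}{'SS':>12}{'df':>6}{'MS':>12}{'F':>10}{'p':>12}"
        ]
        for key, label in (
            ("a", self.factor_a),
            ("b", self.factor_b),
            ("interaction", f"{self.factor_a} x {self.factor_b}"),
            ("error", "error"),
            ("total", "total"),
        ):
            f = self.f_stats.get(key)
            p = self.p_values.get(key)
            lines.append(
                f"{label:<22}{self.ss[key]:>12.4f}{self.df[key]:>6}"
                + (f"{self.ms[key]:>12.4f}" if key in self.ms else " " * 12)
                + (f"{f:>10.3f}" if f is not None else " " * 10)
                + (f"{p:>12.4g}" if p is not None else " " * 12)
            )
        return "\n".join(lines)


def _to_array(
    samples: Iterable[FibreSample],
) -> Tuple[np.ndarray, Tuple[str, ...], Tuple[str, ...]]:
    """Stack samples into an (a, b, n) array, enforcing a balanced design."""
    cells: Dict[Tuple[str, str], List[float]] = {}
    for s in samples:
        cells.setdefault((str(s.compartment), str(s.depth)), []).append(s.length)
    if not cells:
        raise ValueError("no fibre samples supplied")
    levels_a = tuple(sorted({k[0] for k in cells}))
    levels_b = tuple(sorted({k[1] for k in cells}))
    counts = set()
    for la in levels_a:
        for lb in levels_b:
            if (la, lb) not in cells:
                raise ValueError(f"empty design cell: ({la}, {lb})")
            counts.add(len(cells[(la, lb)]))
    if len(counts) != 1:
        raise ValueError(
            "unbalanced design (unequal fibres per cell); the factorial "
            "decomposition is ambiguous — subsample to a common n or "
            "analyse per-slice"
        )
    n = counts.pop()
    if n < 2:
        raise ValueError("need at least two fibres per cell for an error term")
    data = np.array(
        [[cells[(la, lb)] for lb in levels_b] for la in levels_a], dtype=float
    )
    return data, levels_a, levels_b


def two_way_anova_array(data: np.ndarray) -> dict:
    """Balanced two-way ANOVA on an (a, b, n) array (or batched (..., a, b, n)).

    Returns sums of squares, degrees of freedom, F statistics and p-values
    keyed 'a', 'b', 'interaction', 'error', 'total'. Batched leading axes
    are carried through on the statistics, which lets the null-calibration
    simulations run vectorized.
    """
    data = np.asarray(data, dtype=float)
    a, b, n = data.shape[-3:]
    if n < 2:
        raise ValueError("need n >= 2 per cell")
    grand = data.mean(axis=(-3, -2, -1), keepdims=True)
    cell = data.mean(axis=-1, keepdims=True)  # (..., a, b, 1)
    mean_a = data.mean(axis=(-2, -1), keepdims=True)  # (..., a, 1, 1)
    mean_b = data.mean(axis=(-3, -1), keepdims=True)  # (..., 1, b, 1)
    ss_a = b * n * ((mean_a - grand) ** 2).sum(axis=(-3, -2, -1))
    ss_b = a * n * ((mean_b - grand) ** 2).sum(axis=(-3, -2, -1))
    ss_int = n * ((cell - mean_a - mean_b + grand) ** 2).sum(axis=(-3, -2, -1))
    ss_err = ((data - cell) ** 2).sum(axis=(-3, -2, -1))
    ss_tot = ((data - grand) ** 2).sum(axis=(-3, -2, -1))
    df = {
        "a": a - 1,
        "b": b - 1,
        "interaction": (a - 1) * (b - 1),
        "error": a * b * (n - 1),
        "total": a * b * n - 1,
    }
    ms_err = ss_err / df["error"]
    out = {
        "ss": {
            "a": ss_a,
            "b": ss_b,
            "interaction": ss_int,
            "error": ss_err,
            "total": ss_tot,
        },
        "df": df,
        "ms": {
            "a": ss_a / df["a"],
            "b": ss_b / df["b"],
            "interaction": ss_int / df["interaction"],
            "error": ms_err,
        },
        "f": {},
        "p": {},
        "cell_means": cell[..., 0],
    }
    with np.errstate(divide="ignore", invalid="ignore"):
        for key in ("a", "b", "interaction"):
            f = out["ms"][key] / ms_err
            out["f"][key] = f
            out["p"][key] = stats.f.sf(f, df[key], df["error"])
    return out


def two_way_anova(samples: Iterable[FibreSample]) -> AnovaResult:
    """Balanced two-way ANOVA of fibre length by compartment and depth."""
    data, levels_a, levels_b = _to_array(samples)
    r = two_way_anova_array(data)
    scal = lambda d: {k: float(v) for k, v in d.items()}
    return AnovaResult(
        factor_a="compartment",
        factor_b="depth",
        levels_a=levels_a,
        levels_b=levels_b,
        n_per_cell=data.shape[-1],
        ss=scal(r["ss"]),
        df=r["df"],
        ms=scal(r["ms"]),
        f_stats=scal(r["f"]),
        p_values=scal(r["p"]),
        cell_means=r["cell_means"],
    )


def simple_main_effects(
    samples: Iterable[FibreSample],
    factor: str,
    held_level: str,
    *,
    pooled_error: bool = True,
) -> Tuple[float, int, int, float]:
    """Effect of one factor within a fixed level of the other.

    ``factor`` is ``'compartment'`` or ``'depth'``; ``held_level`` names the
    level of the *other* factor to condition on. Returns ``(F, df1, df2, p)``.
    With ``pooled_error=True`` (default) the denominator is the full-model
    error mean square (df2 = full error df); otherwise a one-way error term
    computed within the slice.
    """
    if factor not in ("compartment", "depth"):
        raise ValueError("factor must be 'compartment' or 'depth'")
    data, levels_a, levels_b = _to_array(samples)
    # data axes: (compartment, depth, n)
    if factor == "compartment":
        other_levels, slice_axis = levels_b, 1
    else:
        other_levels, slice_axis = levels_a, 0
    if held_level not in other_levels:
        raise ValueError(
            f"held level {held_level!r} not among {other_levels}"
        )
    idx = other_levels.index(held_level)
    sl = np.take(data, idx, axis=slice_axis)  # (k, n) across tested factor
    k, n = sl.shape
    level_means = sl.mean(axis=1)
    grand = sl.mean()
    ss_effect = n * ((level_means - grand) ** 2).sum()
    df1 = k - 1
    if pooled_error:
        full = two_way_anova_array(data)
        ms_err = float(full["ms"]["error"])
        df2 = full["df"]["error"]
    else:
        ss_err = ((sl - level_means[:, None]) ** 2).sum()
        df2 = k * (n - 1)
        ms_err = ss_err / df2
    f = (ss_effect / df1) / ms_err
    p = float(stats.f.sf(f, df1, df2))
    return float(f), df1, df2, p


def bonferroni(p_values: Sequence[float], m: int) -> List[float]:
    """Bonferroni-adjust raw p-values for a family of ``m`` comparisons."""
    if m < 1:
        raise ValueError("family size m must be >= 1")
    adjusted = []
    for p in p_values:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value outside [0, 1]: {p}")
        adjusted.append(min(1.0, p * m))
    return adjusted


def pairwise_depth_comparisons(
    samples: Iterable[FibreSample],
    *,
    m: int | None = None,
) -> List[dict]:
    """Superficial-vs-deep comparison within each compartment.

    Each comparison is a t-test of the two cell means against the pooled
    full-model error term; p-values are Bonferroni-adjusted with family
    size ``m`` (default: the number of comparisons made).
    """
    data, levels_a, levels_b = _to_array(samples)
    if len(levels_b) != 2:
        raise ValueError("depth comparisons need exactly two depth levels")
    full = two_way_anova_array(data)
    ms_err = float(full["ms"]["error"])
    df_err = full["df"]["error"]
    n = data.shape[-1]
    rows = []
    for i, comp in enumerate(levels_a):
        m1 = data[i, 0].mean()
        m2 = data[i, 1].mean()
        se = np.sqrt(2.0 * ms_err / n)
        t = (m1 - m2) / se
        p = 2.0 * float(stats.t.sf(abs(t), df_err))
        rows.append(
            {
                "compartment": comp,
                "pair": (levels_b[0], levels_b[1]),
                "mean_difference": float(m1 - m2),
                "t": float(t),
                "p_raw": p,
            }
        )
    family = m if m is not None else len(rows)
    for row, p_adj in zip(rows, bonferroni([r["p_raw"] for r in rows], family)):
        row["p_adjusted"] = p_adj
        row["significant"] = p_adj < DEFAULT_CONSTANTS.alpha
    return rows
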
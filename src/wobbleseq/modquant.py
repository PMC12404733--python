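"""I34 stoichiometry and modification signal quantification.

The wobble-inosine stoichiometry of an ANN isodecoder is estimated from its
pileup as theta = G / (G + A) at the wobble position: inosine is read as G by
the reverse transcriptase, unedited adenosine as A.  C and T calls there are
treated as sequencing error and excluded from the denominator.  Confidence
intervals are Wilson 95% intervals (stable near theta = 0 and 1, where
control tRNAs sit -- they are fully deaminated).  Units whose informative
coverage G+A falls below ``min_coverage`` are reported as low_coverage with
no point estimate.

Anticodon-pool estimates are coverage-weighted means of member proportions,
which equal the proportion computed from the pooled G and A counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .reference import ReferenceSet
from .assign import PositionPileup

CALLED, LOW_COVERAGE = "called", "low_coverage"


@dataclass
class ModCall:
    unit: str
    coverage: float  # informative coverage: G + A at the wobble position
    theta: float | None
    ci_low: float | None
    ci_high: float | None
    status: str

    @property
    def called(self) -> bool:
        return self.status == CALLED


def _wilson(g: float, n: float) -> tuple[float, float]:
    lo, hi = proportion_confint(g, n, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def _call_from_counts(unit: str, g: float, a: float, min_coverage: float) -> ModCall:
    n = g + a
    if n < min_coverage:
        return ModCall(unit, n, None, None, None, LOW_COVERAGE)
    lo, hi = _wilson(g, n)
    return ModCall(unit, n, g / n, lo, hi, CALLED)


def call_i34(
    pileups: PositionPileup,
    refset: ReferenceSet,
    min_coverage: float = 20,
    units: list[str] | None = None,
) -> list[ModCall]:
    """Per-isodecoder I34 stoichiometry from wobble-position pileups.

    Only ANN (nuclear, A34) isodecoders are callable; requesting any other
    unit raises.  By default all ANN isodecoders present in the pileup are
    called, in sorted order.
    """
    ann_ids = {r.id for r in refset.ann_records()}
    if units is None:
        units = sorted(ann_ids & set(pileups.base_counts))
    calls = []
    for unit in units:
        if unit not in ann_ids:
            raise ValueError(f"{unit} is not an ANN (ADAT substrate) isodecoder")
        rec = refset.records[unit]
        w = rec.wobble_index
        bc = pileups.base_counts.get(unit)
        g = float(bc[w, 2]) if bc is not None else 0.0
        a = float(bc[w, 0]) if bc is not None else 0.0
        calls.append(_call_from_counts(unit, g, a, min_coverage))
    return calls


def aggregate_anticodon(
    calls: list[ModCall],
    refset: ReferenceSet,
    min_coverage: float = 20,
) -> list[ModCall]:
    """Pool member calls into per-anticodon-family stoichiometries.

    The pool estimate is the coverage-weighted mean of member proportions
    (identically G_sum / (G_sum + A_sum)); the CI comes from the pooled
    counts.  A family with no called member is reported low_coverage.
    """
    by_fam: dict[str, list[ModCall]] = {}
    for call in calls:
        fam = refset.family_of(call.unit).label
        by_fam.setdefault(fam, []).append(call)
    pooled = []
    for fam in sorted(by_fam):
        members = [c for c in by_fam[fam] if c.called]
        if not members:
            cov = sum(c.coverage for c in by_fam[fam])
            pooled.append(ModCall(fam, cov, None, None, None, LOW_COVERAGE))
            continue
        g = sum(c.theta * c.coverage for c in members)
        n = sum(c.coverage for c in members)
        pooled.append(_call_from_counts(fam, g, n - g, min_coverage))
    return pooled


def calls_to_frame(calls: list[ModCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "unit": c.unit,
                "coverage": c.coverage,
                "theta": c.theta,
                "ci_lo": c.ci_low,
                "ci_hi": c.ci_high,
                "status": c.status,
            }
            for c in calls
        ]
    )


def write_calls(calls: list[ModCall], path: str | Path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False, float_format="%.6g")


def delta_mod(
    case_calls: list[ModCall],
    control_calls: list[ModCall],
    floor: float = 1e-3,
) -> pd.DataFrame:
    """Per-unit I34 change, case minus control.

    Returns delta in percentage points and log2(theta_case/theta_control)
    (thetas floored at *floor* so fully lost units keep a finite ratio).
    Units low_coverage on either side are excluded and flagged in the
    ``excluded`` column of the returned frame's attrs.
    """
    case = {c.unit: c for c in case_calls}
    control = {c.unit: c for c in control_calls}
    shared = sorted(set(case) & set(control))
    if not shared:
        raise ValueError("no shared units between case and control calls")
    rows, excluded = [], []
    for unit in shared:
        a, b = case[unit], control[unit]
        if not (a.called and b.called):
            excluded.append(unit)
            continue
        rows.append(
            {
                "unit": unit,
                "theta_case": a.theta,
                "theta_control": b.theta,
                "delta_points": 100.0 * (a.theta - b.theta),
                "delta_log2": float(
                    np.log2(max(a.theta, floor) / max(b.theta, floor))
                ),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["excluded"] = excluded
    return out


# ---------------------------------------------------------------------------
# other-modification profiles (misincorporation + truncation)
# ---------------------------------------------------------------------------

def profile_modifications(
    pileups: PositionPileup, refset: ReferenceSet
) -> pd.DataFrame:
    """Misincorporation and RT-stop proportions at annotated non-I34 sites.

    Misincorporation = non-reference base calls / total base calls at the
    site; truncation = reads starting exactly one base 3' of the site over
    reads that reached the site or stopped there.
    """
    rows = []
    for iso in sorted(pileups.base_counts):
        rec = refset.records[iso]
        bc = pileups.base_counts[iso]
        ts = pileups.trunc_starts[iso]
        for pos, label in rec.mod_sites:
            total = bc[pos].sum()
            ref_idx = "ACGT".index(rec.sequence[pos])
            mis = (total - bc[pos, ref_idx]) / total if total > 0 else np.nan
            stops = ts[pos + 1] if pos + 1 < len(ts) else 0.0
            reached = total + stops
            rows.append(
                {
                    "unit": iso,
                    "pos": pos,
                    "mod": label,
                    "misincorporation": mis,
                    "truncation": stops / reached if reached > 0 else np.nan,
                    "coverage": total,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# in vitro deamination curves
# ---------------------------------------------------------------------------

@dataclass
class DeaminationCurve:
    enzyme: str
    concentrations: tuple[float, ...]
    editing_fraction: tuple[float, ...]
    relative_activity: tuple[float, ...] | None = None  # vs reference enzyme
    percent_change: tuple[float, ...] | None = None


def deamination_curve(
    base_counts: pd.DataFrame, reference_enzyme: str = "WT"
) -> list[DeaminationCurve]:
    """Editing fraction G/(G+A) per enzyme and concentration from an in vitro
    assay base-count table (columns: enzyme, concentration, G, A), plus
    relative activity against *reference_enzyme* at matched concentrations;
    percent change = 100*(ratio - 1).  Rows with G+A = 0 are excluded.
    """
    df = base_counts.copy()
    required = {"enzyme", "concentration", "G", "A"}
    if not required <= set(df.columns):
        raise ValueError(f"assay table needs columns {sorted(required)}")
    df["n"] = df["G"] + df["A"]
    flagged = df[df["n"] <= 0]
    df = df[df["n"] > 0].copy()
    df["fraction"] = df["G"] / df["n"]

    ref = (
        df[df["enzyme"] == reference_enzyme]
        .set_index("concentration")["fraction"]
        .to_dict()
    )
    curves = []
    for enzyme, grp in df.groupby("enzyme", sort=True):
        grp = grp.sort_values("concentration")
        conc = tuple(float(c) for c in grp["concentration"])
        frac = tuple(float(f) for f in grp["fraction"])
        rel = pc = None
        if ref:
            rel = tuple(
                f / ref[c] if c in ref and ref[c] > 0 else np.nan
                for c, f in zip(conc, frac)
            )
            pc = tuple(100.0 * (r - 1.0) if np.isfinite(r) else np.nan for r in rel)
        curves.append(
            DeaminationCurve(
                enzyme=str(enzyme),
                concentrations=conc,
                editing_fraction=frac,
                relative_activity=rel,
                percent_change=pc,
            )
        )
    for curve in curves:
        curve.excluded_rows = len(flagged[flagged["enzyme"] == curve.enzyme])  # type: ignore[attr-defined]
    return curves
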
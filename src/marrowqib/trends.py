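"""RC-thresholded longitudinal change-trend analysis.

A change in a section-mean biomarker between a timepoint and a reference
is called significant, with 95% confidence, when its magnitude exceeds
the section-specific repeatability coefficient: |Δ| > RC (strict).  Two
reference conventions are supported:

* wild-type: the collective section-specific average over all wild-type
  animals (two-level average — within animal over its longitudinal
  scans, then across animals);
* baseline: each animal's earliest QC-passing scan at/after the
  QIB-specific baseline window (weeks 5–6 post-ablation for ADC, whose
  b=3000 acquisition did not exist at weeks 3–4; weeks 3–4 for PDFF and
  MTR).

Cohort tables count, per (QIB, section, timepoint), the number of
animals with significant change over the number with a defined change
("#(>RC)/total"), with a majority flag when the numerator exceeds half
the denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: Earliest week of the baseline reference window, per QIB.
DEFAULT_BASELINE_WEEK = {"ADC": 5.0, "PDFF": 3.0, "MTR": 3.0}


@dataclass
class TrendRecord:
    """Change of one animal's section value vs its reference."""

    animal_id: str
    qib_kind: str
    section: str
    timepoint_weeks: float
    reference_kind: str  # "wildtype" | "baseline"
    delta: float  # NaN when the reference is undefined
    rc_threshold: float
    significant: bool


@dataclass
class WildtypeReference:
    """Collective WT averages per (QIB, section) with diagnostics."""

    reference: dict[tuple[str, str], float]
    per_animal_scan_counts: dict[str, int] = field(default_factory=dict)
    slope_p_values: dict[tuple[str, str], float] = field(default_factory=dict)


def wildtype_reference(wt_scans: pd.DataFrame) -> WildtypeReference:
    """Two-level average of wild-type scans plus a time-trend diagnostic.

    ``wt_scans`` columns: animal_id, qib, section, weeks, value.  Each
    animal's scans are averaged first, so animals with more scans do not
    dominate; an OLS slope test of value vs weeks over all scans is
    reported per stratum as a diagnostic p-value only (no gating).
    """
    required = {"animal_id", "qib", "section", "weeks", "value"}
    if not required.issubset(wt_scans.columns):
        raise ValueError(f"missing columns: {required - set(wt_scans.columns)}")
    if wt_scans.empty:
        raise ValueError("no wild-type scans")
    per_animal = (
        wt_scans.groupby(["qib", "section", "animal_id"])["value"].mean().reset_index()
    )
    collective = per_animal.groupby(["qib", "section"])["value"].mean()
    reference = {(q, s): float(v) for (q, s), v in collective.items()}

    counts = wt_scans.groupby("animal_id").size().to_dict()
    slope_p = {}
    for (q, s), grp in wt_scans.groupby(["qib", "section"]):
        if grp["weeks"].nunique() < 2:
            slope_p[(q, s)] = 1.0
            continue
        res = stats.linregress(grp["weeks"], grp["value"])
        slope_p[(q, s)] = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
    return WildtypeReference(reference, counts, slope_p)


def change_vs_reference(
    value: float,
    reference: float,
    rc_threshold: float,
    animal_id: str = "",
    qib_kind: str = "",
    section: str = "",
    timepoint_weeks: float = float("nan"),
    reference_kind: str = "baseline",
) -> TrendRecord:
    """Δ = value − reference; significant iff |Δ| > RC (strict).

    A missing reference (NaN, e.g. section QC-failed at baseline) yields
    an undefined Δ which is excluded from cohort counts.
    """
    if rc_threshold < 0:
        raise ValueError("rc_threshold must be >= 0")
    if reference is None or not math.isfinite(reference):
        delta, significant = float("nan"), False
    else:
        delta = value - reference
        significant = abs(delta) > rc_threshold
    return TrendRecord(
        animal_id=animal_id,
        qib_kind=qib_kind,
        section=section,
        timepoint_weeks=timepoint_weeks,
        reference_kind=reference_kind,
        delta=delta,
        rc_threshold=rc_threshold,
        significant=significant,
    )


def baseline_policy(
    scans: pd.DataFrame,
    qib_kind: str,
    baseline_weeks: dict[str, float] | None = None,
) -> dict[tuple[str, str], float]:
    """Per (animal, section) baseline reference values for one QIB.

    The reference is the value of the earliest QC-passing scan at/after
    the QIB-specific baseline window start (ties: the earlier scan).
    Animals/sections with no passing scan in or after the window get no
    entry.  ``scans`` columns: animal_id, section, weeks, value, and
    optionally qc_pass.
    """
    weeks0 = (baseline_weeks or DEFAULT_BASELINE_WEEK)[qib_kind]
    df = scans.copy()
    if "qc_pass" in df.columns:
        df = df[df["qc_pass"]]
    df = df[df["weeks"] >= weeks0].sort_values("weeks", kind="stable")
    out = {}
    for (animal, section), grp in df.groupby(["animal_id", "section"]):
        first = grp.iloc[0]
        out[(animal, section)] = float(first["value"])
    return out


def cohort_trends(
    scans: pd.DataFrame,
    rc_by_stratum: dict[tuple[str, str], float],
    reference: WildtypeReference | None = None,
    baseline_weeks: dict[str, float] | None = None,
) -> list[TrendRecord]:
    """Trend records for every scan of a cohort.

    With ``reference`` given, deltas are taken against the collective
    wild-type averages; otherwise against each animal's own baseline
    scan (which itself yields no record).  ``scans`` columns: animal_id,
    qib, section, weeks, value, optional qc_pass.
    """
    records = []
    df = scans
    if "qc_pass" in df.columns:
        df = df[df["qc_pass"]]
    for qib, qgrp in df.groupby("qib"):
        if reference is None:
            base = baseline_policy(qgrp, qib, baseline_weeks)
            weeks0 = (baseline_weeks or DEFAULT_BASELINE_WEEK)[qib]
            eligible = qgrp[qgrp["weeks"] >= weeks0]
            base_week = {
                (animal, section): float(grp["weeks"].min())
                for (animal, section), grp in eligible.groupby(["animal_id", "section"])
            }
        for _, row in qgrp.iterrows():
            key = (qib, row["section"])
            rc_thr = rc_by_stratum[key]
            if reference is not None:
                ref = reference.reference.get(key, float("nan"))
            else:
                ref = base.get((row["animal_id"], row["section"]), float("nan"))
                if (
                    (row["animal_id"], row["section"]) in base_week
                    and row["weeks"] <= base_week[(row["animal_id"], row["section"])]
                ):
                    continue  # the baseline scan itself is not a change record
            records.append(
                change_vs_reference(
                    float(row["value"]),
                    ref,
                    rc_thr,
                    animal_id=row["animal_id"],
                    qib_kind=qib,
                    section=row["section"],
                    timepoint_weeks=float(row["weeks"]),
                    reference_kind="wildtype" if reference is not None else "baseline",
                )
            )
    return records


def cohort_counts(records: list[TrendRecord]) -> pd.DataFrame:
    """"#(>RC)/total" table per (QIB, section, timepoint).

    numerator = significant records; denominator = records with a
    defined delta; ``majority`` mirrors the starred markers (numerator
    strictly exceeding half the denominator).
    """
    rows = []
    groups: dict[tuple, list[TrendRecord]] = {}
    for r in records:
        groups.setdefault((r.qib_kind, r.section, r.timepoint_weeks), []).append(r)
    for (qib, section, weeks), grp in sorted(groups.items()):
        defined = [r for r in grp if math.isfinite(r.delta)]
        n_sig = sum(r.significant for r in defined)
        n_tot = len(defined)
        rows.append(
            dict(
                qib=qib,
                section=section,
                weeks=weeks,
                n_significant=n_sig,
                n_total=n_tot,
                label=f"{n_sig}/{n_tot}",
                majority=n_sig > n_tot / 2 if n_tot else False,
            )
        )
    return pd.DataFrame(rows)
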
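"""Cohort-level statistics over breakpoint and outcome tables.

Operates on the packaged 26-patient tables (or any table in the same
dialect): orientation-type census, three-way translocation detection,
capture-region arithmetic, breakpoint offset distributions, Kaplan-Meier
curves with a two-group log-rank test computed from first principles,
and an exact hypergeometric association test.

Remission time is read as time-to-event for relapsed patients and as
censoring time for patients alive in remission.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

from . import io
from .rearrange import Junction, canonical, classify_type, chrom_sort_key

PRIMARY_PAIR = ("chr12", "chr21")

__all__ = [
    "patients_by_type", "count_types", "find_three_way", "region_stats",
    "breakpoint_offsets", "logrank_test", "hypergeom_association",
    "cohort_summary", "compare_relapse_patterns", "SurvivalResult",
]


def _table_junctions(junction_table) -> list[Junction]:
    if isinstance(junction_table, pd.DataFrame):
        return io.junctions_from_table(junction_table)
    return list(junction_table)


def patients_by_type(junction_table, primary_pair=PRIMARY_PAIR) -> dict[str, set]:
    """Patients carrying >= 1 junction of each orientation type.

    Only junctions with both breakends on the primary chromosome pair are
    typed; a breakend anywhere on those chromosomes counts, whether or
    not it falls inside a capture interval.
    """
    out = {"a": set(), "b": set(), "c": set(), "d": set()}
    primary = set(primary_pair)
    for j in _table_junctions(junction_table):
        if {j.donor.chrom, j.acceptor.chrom} != primary:
            continue
        out[classify_type(j, primary_pair)].add(j.sample)
    return out


def count_types(junction_table, primary_pair=PRIMARY_PAIR) -> dict[str, int]:
    """Patient count per orientation type (patients, not junction rows)."""
    return {t: len(p) for t, p in patients_by_type(junction_table, primary_pair).items()}


def find_three_way(junction_table, primary_pair=PRIMARY_PAIR) -> dict[str, set]:
    """Patients with a breakend beyond the primary pair, with partners."""
    primary = set(primary_pair)
    out: dict[str, set] = {}
    for j in _table_junctions(junction_table):
        partners = {j.donor.chrom, j.acceptor.chrom} - primary
        if partners:
            out.setdefault(j.sample, set()).update(partners)
    return out


def region_stats(target_regions) -> dict:
    """Per-region and total lengths of 1-based inclusive intervals."""
    regions = []
    total = 0
    for chrom, start, end in target_regions:
        if start > end:
            raise ValueError(f"interval start > end: {chrom}:{start}-{end}")
        length = end - start + 1
        total += length
        regions.append({"chrom": chrom, "start": start, "end": end,
                        "length_bp": length,
                        "length_kbp": int((length + 500) // 1000)})
    return {"regions": regions, "total_bp": total,
            "total_kbp": round(total / 1000)}


def breakpoint_offsets(junction_table, target_regions) -> pd.DataFrame:
    """Offsets of breakpoints from the start of their capture region.

    ``offset = position - region_start + 1``; breakends outside every
    region on their chromosome are flagged rather than dropped.
    """
    by_chrom: dict[str, list] = {}
    for chrom, start, end in target_regions:
        by_chrom.setdefault(chrom, []).append((start, end))
    rows = []
    for j in _table_junctions(junction_table):
        for side, be in (("donor", j.donor), ("acceptor", j.acceptor)):
            regions = by_chrom.get(be.chrom, [])
            hit = next(((s, e) for s, e in regions if s <= be.pos <= e), None)
            if hit:
                rows.append({"sample": j.sample, "side": side, "chrom": be.chrom,
                             "pos": be.pos, "offset": be.pos - hit[0] + 1,
                             "in_region": True})
            else:
                off = be.pos - regions[0][0] + 1 if regions else np.nan
                rows.append({"sample": j.sample, "side": side, "chrom": be.chrom,
                             "pos": be.pos, "offset": off, "in_region": False})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

@dataclass
class SurvivalResult:
    chi_square: float
    p_value: float
    observed: dict[str, float]
    expected: dict[str, float]
    variance: float
    km_curves: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)


def _km_curve(times, events):
    """Kaplan-Meier step function (times, survival) including t=0."""
    order = np.argsort(times, kind="stable")
    times, events = np.asarray(times)[order], np.asarray(events)[order]
    uniq = np.unique(times[events.astype(bool)])
    surv, s = [1.0], 1.0
    ts = [0.0]
    for t in uniq:
        n = np.sum(times >= t)
        d = np.sum((times == t) & events.astype(bool))
        s *= 1.0 - d / n
        ts.append(float(t))
        surv.append(s)
    return np.asarray(ts), np.asarray(surv)


def logrank_test(patients, groups) -> SurvivalResult:
    """Two-group log-rank test computed from first principles.

    ``patients`` is a table with ``POND_id``, ``Outcome`` (``Relapse`` =
    event, ``Alive`` = censored) and ``Remission_days``; ``groups`` maps
    patient id to a group label (exactly two labels).  At every distinct
    event time the observed events in group 1 are compared with their
    hypergeometric expectation given the risk sets; the statistic is
    referred to chi-square with 1 df (two-sided).
    """
    df = patients if isinstance(patients, pd.DataFrame) else pd.DataFrame(patients)
    label = df["POND_id"].map(lambda p: groups.get(p) if isinstance(groups, dict) else None)
    if not isinstance(groups, dict):
        label = pd.Series(list(groups), index=df.index)
    names = sorted(set(label.dropna()), key=str)
    if len(names) != 2:
        raise ValueError(f"need exactly two groups, got {names}")
    times = df["Remission_days"].to_numpy(dtype=float)
    events = (df["Outcome"].astype(str).str.strip() == "Relapse").to_numpy()
    g1 = (label == names[1]).to_numpy()
    if (~g1).sum() == 0 or g1.sum() == 0:
        raise ValueError("a group has zero members")
    if not events.any():
        raise ValueError("no events")

    O1 = E1 = V = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & g1).sum()
        O1 += d1
        E1 += d * n1 / n
        if n > 1:
            V += d * (n - d) * n1 * (n - n1) / (n ** 2 * (n - 1))
    chi2 = (O1 - E1) ** 2 / V if V > 0 else 0.0
    p = float(stats.chi2.sf(chi2, df=1))
    O_total = events.sum()
    curves = {
        names[0]: _km_curve(times[~g1], events[~g1]),
        names[1]: _km_curve(times[g1], events[g1]),
    }
    return SurvivalResult(
        chi_square=float(chi2), p_value=p,
        observed={names[0]: float(O_total - O1), names[1]: float(O1)},
        expected={names[0]: float(O_total - E1), names[1]: float(E1)},
        variance=float(V), km_curves=curves)


def hypergeom_association(n_total: int, n_group: int, n_events: int,
                          n_events_in_group: int) -> float:
    """One-sided exact tail probability P(X >= observed), X hypergeometric.

    Probability of seeing at least ``n_events_in_group`` of the
    ``n_events`` event patients inside a group of ``n_group`` when events
    are exchangeable across the ``n_total`` cohort.
    """
    if not (0 <= n_group <= n_total and 0 <= n_events <= n_total):
        raise ValueError("inconsistent counts")
    if n_events_in_group > min(n_group, n_events) or n_events_in_group < 0:
        raise ValueError("inconsistent counts")
    denom = math.comb(n_total, n_events)
    total = Fraction(0)
    for k in range(n_events_in_group, min(n_group, n_events) + 1):
        total += Fraction(math.comb(n_group, k)
                          * math.comb(n_total - n_group, n_events - k), denom)
    return float(total)


def cohort_summary(patient_table=None) -> dict:
    """Cohort size, mean age (half-up, 1 decimal), sex and outcome counts."""
    df = (patient_table if isinstance(patient_table, pd.DataFrame)
          else io.read_patient_table(patient_table))
    ages = pd.to_numeric(df["Age_years"], errors="coerce")
    excluded = int(ages.isna().sum())
    mean_age = float(Decimal(str(ages.mean())).quantize(Decimal("0.1"),
                                                        rounding=ROUND_HALF_UP))
    gender = df["Gender"].astype(str).str.strip().str.lower()
    outcome = df["Outcome"].astype(str).str.strip()
    return {
        "n": int(len(df)),
        "mean_age_years": mean_age,
        "boys": int((gender == "male").sum()),
        "girls": int((gender == "female").sum()),
        "relapses": int((outcome == "Relapse").sum()),
        "rows_excluded_missing_age": excluded,
    }


def compare_relapse_patterns(relapse_table=None) -> dict[str, "object"]:
    """Diagnosis-vs-relapse clone verdicts from a translocation-pattern table.

    Patterns like ``t(12;21);t(5;12)`` carry no coordinates, so each
    translocation is lifted to a placeholder junction keyed by its
    chromosome pair and compared coordinate-only.
    """
    from .rearrange import Breakend, SampleCallset, compare_clones

    df = (relapse_table if isinstance(relapse_table, pd.DataFrame)
          else io.read_relapse_table(relapse_table))

    import re

    def to_callset(pid: str, spec: str) -> SampleCallset:
        junctions = []
        for a, b in re.findall(r"t\((\w+);(\w+)\)", str(spec)):
            junctions.append(Junction(Breakend(f"chr{a}", 1, "F"),
                                      Breakend(f"chr{b}", 1, "R"), sample=pid))
        return SampleCallset(pid, junctions)

    out = {}
    for _, row in df.iterrows():
        pid = row["Patient"]
        cmp = compare_clones(to_callset(pid, row["Translocation_diagnosis"]),
                             to_callset(pid, row["Translocation_relapse"]))
        out[pid] = cmp
    return out


def full_report(patient_table=None, junction_table=None,
                target_regions=None) -> dict:
    """One JSON-serializable report with every cohort statistic."""
    pdf = (patient_table if isinstance(patient_table, pd.DataFrame)
           else io.read_patient_table(patient_table))
    jdf = (junction_table if isinstance(junction_table, pd.DataFrame)
           else io.read_junction_table(junction_table))
    if target_regions is None:
        from .rearrange import HG19_MODEL
        target_regions = HG19_MODEL.target_regions
    by_type = patients_by_type(jdf)
    three_way = find_three_way(jdf)
    groups = {pid: ("three_way" if pid in three_way else "two_way")
              for pid in pdf["POND_id"]}
    surv = logrank_test(pdf, groups)
    n_events = int((pdf["Outcome"].astype(str).str.strip() == "Relapse").sum())
    n_events_3w = sum(1 for pid in three_way
                      if groups.get(pid) == "three_way"
                      and (pdf.set_index("POND_id").loc[pid, "Outcome"] == "Relapse"))
    relapse_cmp = compare_relapse_patterns()
    return {
        "summary": cohort_summary(pdf),
        "type_counts": count_types(jdf),
        "patients_with_c_and_d": len(by_type["c"] & by_type["d"]),
        "three_way": {pid: sorted(p, key=chrom_sort_key)
                      for pid, p in sorted(three_way.items())},
        "regions": region_stats(target_regions),
        "logrank": {"chi_square": surv.chi_square, "p_value": surv.p_value,
                    "observed": surv.observed, "expected": surv.expected},
        "hypergeometric_p": hypergeom_association(
            len(pdf), len(three_way), n_events, n_events_3w),
        "relapse_comparison": {pid: c.relation for pid, c in relapse_cmp.items()},
    }
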
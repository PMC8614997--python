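"""Host-range and virulence statistics from plate and spot-assay data.

Implements the standard phenotypic read-outs of phage characterization
on a strain panel:

* **OD ratio** -- OD600 of a phage-treated culture over its untreated
  control; a ratio below 0.1 (strict) counts as *no growth*.
* **KHR** (kinetic host range) -- percent of strains suppressed in
  suspension at a timepoint, per replicate, with mean +/- SD and a
  per-strain replicate-consensus code (2/2, 1/2, 0/2).
* **PHR** (plaquing host range) -- percent of strains with *clear*
  plaques; opaque lysis (growth impairment without clear plaques) does
  not count.
* **EOP** (efficiency of plating) -- PFU on a test strain over PFU on
  the propagation host.
* **MOI virulence profiles** -- percent of strains suppressed at 24 h
  per multiplicity of infection.
* **EOP vs OD-ratio association** -- Spearman rank correlation with a
  seeded permutation p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import PlateMeasurement, SpotResult

__all__ = [
    "od_ratio",
    "classify_growth",
    "compute_khr",
    "compute_phr",
    "compute_eop",
    "virulence_profile",
    "correlate_eop_odratio",
    "KhrResult",
    "PhrResult",
    "EopResult",
    "SpearmanResult",
    "measurements_to_frame",
    "read_plate_tsv",
    "write_plate_tsv",
    "read_spot_tsv",
    "write_spot_tsv",
]

GROWTH_THRESHOLD = 0.1
CONTROL = "CONTROL"

PLATE_COLUMNS = ["strain", "phage", "timepoint_h", "replicate", "od600", "moi"]
SPOT_COLUMNS = ["strain", "phage", "outcome", "pfu_per_ml"]


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def od_ratio(treated: float, control: float) -> float:
    """Growth ratio of a treated well relative to its untreated control."""
    if control <= 0:
        raise ValueError(f"degenerate control well: OD600 {control} is not positive")
    return treated / control


def classify_growth(ratio: float, threshold: float = GROWTH_THRESHOLD) -> str:
    """'suppressed' iff the OD ratio is strictly below the threshold."""
    if ratio < 0:
        raise ValueError("OD ratio cannot be negative")
    return "suppressed" if ratio < threshold else "growth"


@dataclass(frozen=True)
class EopResult:
    value: float
    below_detection: bool = False


def compute_eop(pfu_test: float, pfu_reference: float) -> EopResult:
    """Efficiency of plating: test-strain titer over propagation-host titer."""
    if pfu_reference <= 0:
        raise ValueError("propagation host titer must be positive (it must plaque)")
    if pfu_test < 0:
        raise ValueError("PFU counts cannot be negative")
    if pfu_test == 0:
        return EopResult(0.0, below_detection=True)
    return EopResult(pfu_test / pfu_reference)


# ---------------------------------------------------------------------------
# tabular plumbing
# ---------------------------------------------------------------------------

def measurements_to_frame(measurements: Iterable[PlateMeasurement]) -> pd.DataFrame:
    rows = [
        (m.strain, m.phage, m.timepoint_h, m.replicate, m.od600, m.moi) for m in measurements
    ]
    df = pd.DataFrame(rows, columns=PLATE_COLUMNS)
    if df.empty:
        raise ValueError("no plate measurements provided")
    if (df["od600"] < 0).any():
        raise ValueError("OD600 readings cannot be negative")
    return df


def write_plate_tsv(path: str | Path, measurements: Iterable[PlateMeasurement]) -> None:
    measurements_to_frame(measurements).to_csv(path, sep="\t", index=False)


def read_plate_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(PLATE_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: plate table missing columns {sorted(missing)}")
    if "moi" not in df.columns:
        df["moi"] = np.nan
    if df.empty:
        raise ValueError(f"{path}: plate table has no data rows")
    return df


def write_spot_tsv(path: str | Path, spots: Iterable[SpotResult]) -> None:
    rows = [(s.strain, s.phage, s.outcome, s.pfu_per_ml) for s in spots]
    pd.DataFrame(rows, columns=SPOT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_spot_tsv(path: str | Path) -> list[SpotResult]:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(SPOT_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: spot table missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        pfu = getattr(row, "pfu_per_ml", None)
        out.append(
            SpotResult(row.strain, row.phage, row.outcome, None if pd.isna(pfu) else float(pfu))
        )
    return out


def _as_frame(measurements) -> pd.DataFrame:
    if isinstance(measurements, pd.DataFrame):
        return measurements
    return measurements_to_frame(measurements)


def _ratios(
    df: pd.DataFrame, timepoint: int, *, require_moi: bool = False
) -> pd.DataFrame:
    """Per (strain, phage, replicate[, moi]) OD ratios vs matched controls."""
    at_tp = df[df["timepoint_h"] == timepoint]
    keys = ["strain", "replicate"] + (["moi"] if require_moi else [])
    controls = (
        at_tp[at_tp["phage"] == CONTROL].groupby(keys)["od600"].mean().rename("control_od")
    )
    treated = at_tp[at_tp["phage"] != CONTROL].copy()
    merged = treated.merge(controls, left_on=keys, right_index=True, how="left")
    missing = merged[merged["control_od"].isna()]
    if not missing.empty:
        row = missing.iloc[0]
        raise ValueError(
            f"missing control well for strain {row['strain']!r}, replicate "
            f"{row['replicate']}, timepoint {timepoint} h"
        )
    merged["ratio"] = [
        od_ratio(t, c) for t, c in zip(merged["od600"], merged["control_od"])
    ]
    return merged


# ---------------------------------------------------------------------------
# KHR
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KhrResult:
    """Kinetic host range of one phage at one timepoint."""

    phage: str
    timepoint_h: int
    per_replicate: Mapping[int, float]  # replicate -> KHR percent
    mean: float
    sd: float
    consensus: Mapping[str, int]  # strain -> number of suppressed replicates
    n_replicates: int

    def consensus_code(self, strain: str) -> str:
        """Fig-4-style code: suppressed replicates out of total (e.g. '2/2')."""
        return f"{self.consensus[strain]}/{self.n_replicates}"


def compute_khr(
    measurements,
    timepoint_h: int = 24,
    threshold: float = GROWTH_THRESHOLD,
) -> dict[str, KhrResult]:
    """KHR per phage: percent of strains suppressed, by replicate.

    The headline number is the mean over replicates (+/- sample SD);
    the per-strain consensus matrix counts in how many replicates each
    strain was suppressed.
    """
    df = _as_frame(measurements)
    merged = _ratios(df, timepoint_h)
    if merged.empty:
        raise ValueError(f"no phage-treated wells at {timepoint_h} h")
    merged["suppressed"] = merged["ratio"] < threshold

    results = {}
    for phage, sub in merged.groupby("phage"):
        by_rep = sub.groupby("replicate")["suppressed"]
        per_replicate = {int(rep): 100.0 * grp.mean() for rep, grp in by_rep}
        values = np.array(list(per_replicate.values()))
        consensus = sub.groupby("strain")["suppressed"].sum().astype(int).to_dict()
        results[phage] = KhrResult(
            phage=phage,
            timepoint_h=timepoint_h,
            per_replicate=per_replicate,
            mean=float(values.mean()),
            sd=float(values.std(ddof=1)) if len(values) > 1 else 0.0,
            consensus=consensus,
            n_replicates=len(per_replicate),
        )
    return results


# ---------------------------------------------------------------------------
# PHR
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhrResult:
    phage: str
    percent: float
    per_strain: Mapping[str, str]  # strain -> outcome


def compute_phr(spots: Sequence[SpotResult]) -> PhrResult:
    """Plaquing host range: percent of strains with clear plaques.

    Opaque lysis counts as negative.  The input must describe a single
    phage with one row per strain.
    """
    if not spots:
        raise ValueError("no spot results provided")
    phages = {s.phage for s in spots}
    if len(phages) > 1:
        raise ValueError(f"spot table mixes phages {sorted(phages)}; compute one at a time")
    seen: dict[str, str] = {}
    for s in spots:
        if s.strain in seen:
            raise ValueError(f"duplicate strain {s.strain!r} in spot table")
        if s.outcome not in ("clear", "opaque", "none"):
            raise ValueError(f"invalid spot outcome {s.outcome!r} for strain {s.strain!r}")
        seen[s.strain] = s.outcome
    clear = sum(1 for outcome in seen.values() if outcome == "clear")
    return PhrResult(phage=next(iter(phages)), percent=100.0 * clear / len(seen), per_strain=seen)


# ---------------------------------------------------------------------------
# MOI virulence profile
# ---------------------------------------------------------------------------

def virulence_profile(
    measurements,
    threshold: float = GROWTH_THRESHOLD,
    timepoint_h: int = 24,
) -> dict[str, dict[float, float]]:
    """Percent of strains suppressed per MOI, per phage, at 24 h.

    Replicates are aggregated by majority vote per strain; ties count as
    not suppressed.  MOI levels without control wells are omitted with a
    warning.
    """
    df = _as_frame(measurements)
    if df["moi"].isna().all():
        raise ValueError("plate table has no MOI annotations")
    try:
        merged = _ratios(df, timepoint_h, require_moi=True)
    except ValueError:
        # fall back level-by-level so one bad MOI level doesn't kill the rest
        merged = None
    if merged is None:
        parts = []
        for moi in sorted(df["moi"].dropna().unique()):
            sub = df[df["moi"] == moi]
            try:
                parts.append(_ratios(sub, timepoint_h, require_moi=True))
            except ValueError as exc:
                warnings.warn(f"MOI {moi} omitted: {exc}", stacklevel=2)
        if not parts:
            raise ValueError("no MOI level has complete control wells")
        merged = pd.concat(parts, ignore_index=True)

    merged["suppressed"] = merged["ratio"] < threshold
    profile: dict[str, dict[float, float]] = {}
    for (phage, moi), sub in merged.groupby(["phage", "moi"]):
        votes = sub.groupby("strain")["suppressed"].agg(["sum", "count"])
        majority = votes["sum"] * 2 > votes["count"]  # tie -> not suppressed
        profile.setdefault(phage, {})[float(moi)] = 100.0 * majority.mean()
    for phage in profile:
        profile[phage] = dict(sorted(profile[phage].items(), reverse=True))
    return profile


# ---------------------------------------------------------------------------
# EOP vs OD-ratio association
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    n: int
    degenerate: bool = False
    significant: bool = field(default=False)


def correlate_eop_odratio(
    eop: Mapping[str, float],
    od_ratio_24h: Mapping[str, float],
    n_permutations: int = 10000,
    seed: int = 0,
    *,
    pseudo_floor: float | None = None,
    alpha: float = 0.05,
) -> SpearmanResult:
    """Spearman correlation of log-EOP with the 24 h OD ratio.

    EOP zeros are floored at one tenth of the smallest positive value
    (the nominal detection limit) before log transformation; the rank
    correlation is otherwise transform-invariant.  The p-value comes
    from ``n_permutations`` seeded label permutations.  Constant inputs
    are reported as degenerate/not significant rather than an error.
    """
    strains = sorted(set(eop) & set(od_ratio_24h))
    if len(strains) < 3:
        raise ValueError(f"need >=3 paired strains, got {len(strains)}")
    e = np.array([eop[s] for s in strains], dtype=float)
    r = np.array([od_ratio_24h[s] for s in strains], dtype=float)
    if (e < 0).any() or (r < 0).any():
        raise ValueError("EOP and OD ratios must be non-negative")

    positive = e[e > 0]
    if pseudo_floor is None:
        pseudo_floor = positive.min() / 10.0 if positive.size else 1.0
    log_e = np.log10(np.where(e > 0, e, pseudo_floor))

    if np.unique(log_e).size < 2 or np.unique(r).size < 2:
        return SpearmanResult(float("nan"), 1.0, len(strains), degenerate=True)

    x = stats.rankdata(log_e)
    y = stats.rankdata(r)
    rho = float(stats.spearmanr(log_e, r).statistic)

    rng = np.random.default_rng(seed)
    xc = x - x.mean()
    xn = np.linalg.norm(xc)
    perms = np.array([rng.permutation(y) for _ in range(n_permutations)])
    yc = perms - perms.mean(axis=1, keepdims=True)
    rhos = (yc @ xc) / (np.linalg.norm(yc, axis=1) * xn)
    p = (1 + np.sum(np.abs(rhos) >= abs(rho) - 1e-12)) / (n_permutations + 1)
    return SpearmanResult(rho, float(p), len(strains), significant=p < alpha)
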
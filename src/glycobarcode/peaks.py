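"""Peak-table ingestion, cross-run alignment, feature filtering and QC-pool normalization.

One LC-MS run exports a peak list (retention time in minutes, m/z in Da, peak
area, optional vendor signal-to-noise). Runs are aligned into a samples x
features matrix by clustering peak positions within fixed tolerances, the
feature set is pruned by a three-step filter (QC reproducibility, S/N,
isotope/adduct/fragment removal), and expression is reported as the ratio of
each sample's area to the mean area of the QC-pool injections that bracket it
in run order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default cross-run alignment tolerances.
RT_TOL = 0.5  # minutes
MZ_TOL = 0.08  # Da

#: Mass difference between successive isotopologues (Da).
ISOTOPE_SPACING = 1.003355

#: Default adduct mass offsets for negative-mode electrospray (Da).
NEG_MODE_ADDUCTS = {
    "Na-H": 21.9819,
    "2Na-2H": 35.9767,
    "formate": 46.0055,
    "acetate": 59.0133,
}


@dataclass(frozen=True)
class Peak:
    """A single chromatographic peak: position (rt, mz) and intensity (area)."""

    rt: float
    mz: float
    area: float
    snr: float | None = None

    def __post_init__(self) -> None:
        if self.rt < 0:
            raise ValueError(f"rt must be >= 0, got {self.rt}")
        if self.mz <= 0:
            raise ValueError(f"mz must be > 0, got {self.mz}")
        if self.area < 0:
            raise ValueError(f"area must be >= 0, got {self.area}")
        if self.snr is not None and self.snr < 0:
            raise ValueError(f"snr must be >= 0, got {self.snr}")


@dataclass
class PeakTable:
    """One run's peak list, sorted by (rt, mz) on construction."""

    sample_id: str
    role: str  # "patient" or "qc"
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.role not in ("patient", "qc"):
            raise ValueError(f"role must be 'patient' or 'qc', got {self.role!r}")
        self.peaks = sorted(self.peaks, key=lambda p: (p.rt, p.mz))

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class FeatureMatrix:
    """Samples x features expression values plus per-feature (rt, mz) metadata.

    ``values`` is a DataFrame indexed by sample id with feature-id columns
    ("F{rt:.2f}_{mz:.4f}"). ``feature_meta`` is indexed by feature id with
    columns ``rt``, ``mz`` and ``snr`` (median vendor S/N, NaN when absent).
    ``stage`` tracks the processing state: raw areas, filtered areas, or
    QC-ratio normalized expression.
    """

    values: pd.DataFrame
    feature_meta: pd.DataFrame
    stage: str = "raw"
    roles: pd.Series | None = None  # sample -> {patient, qc}
    run_order: pd.Series | None = None  # sample -> injection position

    def __post_init__(self) -> None:
        if self.stage not in ("raw", "filtered", "normalized"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if list(self.values.columns) != list(self.feature_meta.index):
            raise ValueError("values columns and feature_meta index disagree")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def qc_ids(self) -> list[str]:
        if self.roles is None:
            return []
        return list(self.roles.index[self.roles == "qc"])

    def to_csv(self, values_path: str | Path, meta_path: str | Path) -> None:
        self.values.to_csv(values_path, index_label="sample_id")
        self.feature_meta.to_csv(meta_path, index_label="feature_id")

    @classmethod
    def from_csv(
        cls, values_path: str | Path, meta_path: str | Path, stage: str = "normalized"
    ) -> "FeatureMatrix":
        values = pd.read_csv(values_path, index_col="sample_id")
        meta = pd.read_csv(meta_path, index_col="feature_id")
        return cls(values=values, feature_meta=meta, stage=stage)


def feature_id(rt: float, mz: float) -> str:
    return f"F{rt:.2f}_{mz:.4f}"


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_peak_table(path: str | Path, sample_id: str, role: str = "patient") -> PeakTable:
    """Read one delimited peak list (columns rt, mz, area[, snr])."""
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower().strip(): c for c in df.columns}
    for required in ("rt", "mz", "area"):
        if required not in cols:
            raise ValueError(f"{path}: missing column {required!r}")
    has_snr = "snr" in cols
    peaks = [
        Peak(
            rt=float(row[cols["rt"]]),
            mz=float(row[cols["mz"]]),
            area=float(row[cols["area"]]),
            snr=float(row[cols["snr"]]) if has_snr and not pd.isna(row[cols["snr"]]) else None,
        )
        for _, row in df.iterrows()
    ]
    return PeakTable(sample_id=sample_id, role=role, peaks=peaks)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read the sample manifest: sample_id, path, role, label, ca125, he4, run_order."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    for required in ("sample_id", "path", "role"):
        if required not in df.columns:
            raise ValueError(f"manifest missing column {required!r}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in manifest: {dupes}")
    return df


def load_study(manifest_path: str | Path) -> tuple[list[PeakTable], pd.DataFrame]:
    """Load every peak table referenced by a manifest (paths relative to it)."""
    manifest = read_manifest(manifest_path)
    base = Path(manifest_path).parent
    tables = []
    for _, row in manifest.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = base / p
        tables.append(read_peak_table(p, sample_id=row["sample_id"], role=row["role"]))
    return tables, manifest


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def align_peaks(
    tables: Sequence[PeakTable],
    rt_tol: float = RT_TOL,
    mz_tol: float = MZ_TOL,
    manifest: pd.DataFrame | None = None,
) -> FeatureMatrix:
    """Cluster peaks across runs into consensus features and build the raw matrix.

    Greedy centroid clustering: peaks are visited in descending area order
    (ties broken by (rt, mz)); a peak joins the nearest existing consensus
    within ``rt_tol`` and ``mz_tol`` (distance scaled by the tolerances) or
    seeds a new feature at its own (rt, mz). Each sample contributes at most
    one peak per feature — the nearest in scaled (rt, mz) wins. Unmatched
    cells are 0 (absence = no signal).
    """
    if rt_tol <= 0 or mz_tol <= 0:
        raise ValueError("tolerances must be positive")
    if not tables:
        raise ValueError("no peak tables to align")
    ids = [t.sample_id for t in tables]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id among peak tables")
    if all(len(t) == 0 for t in tables):
        raise ValueError("all peak tables are empty")

    # Flatten to arrays; global sort makes the result independent of table order.
    recs = [
        (p.area, p.rt, p.mz, np.nan if p.snr is None else p.snr, si)
        for si, t in enumerate(tables)
        for p in t.peaks
    ]
    arr = np.array(recs, dtype=float)
    order = np.lexsort((arr[:, 2], arr[:, 1], -arr[:, 0]))  # area desc, then rt, mz
    arr = arr[order]

    # Greedy centroid clustering with (rt, mz) bucket hashing: a feature
    # within tolerance of a peak must live in one of the 9 neighboring
    # buckets of side (rt_tol, mz_tol).
    cons_rt: list[float] = []
    cons_mz: list[float] = []
    buckets: dict[tuple[int, int], list[int]] = {}
    assign = np.full(len(arr), -1, dtype=int)
    for i, (area, rt, mz, snr, si) in enumerate(arr):
        brt, bmz = int(rt / rt_tol), int(mz / mz_tol)
        best, best_d = -1, np.inf
        for key in (
            (brt + dr, bmz + dm) for dr in (-1, 0, 1) for dm in (-1, 0, 1)
        ):
            for f in buckets.get(key, ()):
                drt = abs(rt - cons_rt[f])
                dmz = abs(mz - cons_mz[f])
                if drt <= rt_tol and dmz <= mz_tol:
                    d = (drt / rt_tol) ** 2 + (dmz / mz_tol) ** 2
                    if d < best_d:
                        best, best_d = f, d
        if best < 0:
            cons_rt.append(rt)
            cons_mz.append(mz)
            best = len(cons_rt) - 1
            buckets.setdefault((brt, bmz), []).append(best)
        assign[i] = best

    n_feat = len(cons_rt)
    n_samp = len(tables)
    areas = np.zeros((n_samp, n_feat))
    dists = np.full((n_samp, n_feat), np.inf)
    snrs: list[list[float]] = [[] for _ in range(n_feat)]
    for i, (area, rt, mz, snr, si) in enumerate(arr):
        f = assign[i]
        s = int(si)
        d = ((rt - cons_rt[f]) / rt_tol) ** 2 + ((mz - cons_mz[f]) / mz_tol) ** 2
        if d < dists[s, f]:  # nearest peak per (sample, feature) wins
            dists[s, f] = d
            areas[s, f] = area
        if not math.isnan(snr):
            snrs[f].append(snr)

    feat_order = np.lexsort((cons_mz, cons_rt))
    meta = pd.DataFrame(
        {
            "rt": np.asarray(cons_rt)[feat_order],
            "mz": np.asarray(cons_mz)[feat_order],
            "snr": [float(np.median(snrs[f])) if snrs[f] else np.nan for f in feat_order],
        },
        index=[feature_id(cons_rt[f], cons_mz[f]) for f in feat_order],
    )
    values = pd.DataFrame(areas[:, feat_order], index=ids, columns=meta.index)
    roles = pd.Series({t.sample_id: t.role for t in tables})
    run_order = None
    if manifest is not None and "run_order" in manifest.columns:
        run_order = manifest.set_index("sample_id")["run_order"].astype(float)
    return FeatureMatrix(values=values, feature_meta=meta, stage="raw", roles=roles, run_order=run_order)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

@dataclass
class DeisotopeRules:
    """Rule set flagging isotope, adduct and fragment features.

    A feature B is flagged as an isotope of a heavier-intensity feature A when
    it co-elutes (|drt| <= rt_tol), sits one isotope spacing above A's m/z for
    charge z in ``charges`` (|mz_B - mz_A - 1.003355/z| <= mz_tol), and has
    the smaller area. Adducts use a delta-mass list (negative-mode defaults).
    Fragments are co-eluting features whose areas correlate across samples at
    >= ``fragment_corr`` with a higher-m/z feature; the highest-m/z member of
    such a group is kept. Each rule can be switched off.
    """

    rt_tol: float = RT_TOL
    mz_tol: float = MZ_TOL
    charges: tuple[int, ...] = (1, 2, 3)
    adduct_deltas: dict[str, float] = field(default_factory=lambda: dict(NEG_MODE_ADDUCTS))
    fragment_corr: float = 0.95
    isotopes: bool = True
    adducts: bool = True
    fragments: bool = True


@dataclass
class FilterReport:
    n_input: int
    removed_cv: int
    removed_snr: int
    removed_ions: int
    n_output: int
    snr_skipped: bool = False

    def __str__(self) -> str:
        lines = [
            f"input features: {self.n_input}",
            f"step 1 (QC CV): removed {self.removed_cv}",
            f"step 2 (S/N): removed {self.removed_snr}"
            + (" [skipped: no S/N column]" if self.snr_skipped else ""),
            f"step 3 (isotope/adduct/fragment): removed {self.removed_ions}",
            f"output features: {self.n_output}",
        ]
        return "\n".join(lines)


def _qc_cv(areas: np.ndarray) -> float:
    """Coefficient of variation across QC replicates (sample sd / mean)."""
    m = areas.mean()
    if m == 0:
        return np.inf
    return areas.std(ddof=1) / m


def _flag_ions(matrix: FeatureMatrix, rules: DeisotopeRules, ref_area: np.ndarray) -> np.ndarray:
    """Return a boolean mask of features flagged by the deisotoping rules.

    Candidate pairs are found per mass offset through a sorted-m/z window
    (searchsorted) rather than an all-pairs scan.
    """
    meta = matrix.feature_meta
    rt = meta["rt"].to_numpy()
    mz = meta["mz"].to_numpy()
    n = len(meta)
    flagged = np.zeros(n, dtype=bool)
    mz_order = np.argsort(mz, kind="stable")
    mz_sorted = mz[mz_order]

    offsets: list[float] = []
    if rules.isotopes:
        offsets += [ISOTOPE_SPACING / z for z in rules.charges]
    if rules.adducts:
        offsets += list(rules.adduct_deltas.values())
    # isotope/adduct: B flagged when a co-eluting A sits one offset below B's
    # m/z with the larger reference area
    for off in offsets:
        lo = np.searchsorted(mz_sorted, mz - off - rules.mz_tol, side="left")
        hi = np.searchsorted(mz_sorted, mz - off + rules.mz_tol, side="right")
        for b in range(n):
            if flagged[b] or lo[b] >= hi[b]:
                continue
            cand = mz_order[lo[b] : hi[b]]
            cand = cand[cand != b]
            if np.any(
                (np.abs(rt[cand] - rt[b]) <= rules.rt_tol)
                & (ref_area[cand] > ref_area[b])
            ):
                flagged[b] = True

    if rules.fragments and matrix.values.shape[0] >= 3:
        vals = matrix.values.to_numpy(dtype=float)
        sd = vals.std(axis=0, ddof=1)
        nz = sd > 0
        z = np.zeros_like(vals)
        z[:, nz] = (vals[:, nz] - vals[:, nz].mean(axis=0)) / sd[nz]
        denom = vals.shape[0] - 1
        rt_order = np.argsort(rt, kind="stable")
        rt_sorted = rt[rt_order]
        lo = np.searchsorted(rt_sorted, rt - rules.rt_tol, side="left")
        hi = np.searchsorted(rt_sorted, rt + rules.rt_tol, side="right")
        # visit features from high to low m/z so kept high-m/z members are settled first
        for b in sorted(range(n), key=lambda i: -mz[i]):
            if flagged[b] or not nz[b]:
                continue
            cand = rt_order[lo[b] : hi[b]]
            cand = cand[(mz[cand] > mz[b]) & ~flagged[cand] & nz[cand]]
            if len(cand) == 0:
                continue
            corr = z[:, cand].T @ z[:, b] / denom
            if np.any(corr >= rules.fragment_corr):
                flagged[b] = True  # keep the highest-m/z member of the group
    return flagged


def filter_features(
    matrix: FeatureMatrix,
    qc_ids: Sequence[str],
    cv_max: float = 0.50,
    snr_min: float = 5.0,
    rules: DeisotopeRules | None = None,
) -> tuple[FeatureMatrix, FilterReport]:
    """Three-step feature filter: (1) QC reproducibility (CV), (2) S/N, (3) ion curation.

    Retained features have CV over QC replicate areas <= ``cv_max``, median
    vendor S/N >= ``snr_min`` (skipped with a warning when no S/N was
    supplied), and are not flagged as isotope/adduct/fragment ions.
    """
    qc_ids = list(qc_ids)
    missing = [q for q in qc_ids if q not in matrix.values.index]
    if missing:
        raise ValueError(f"QC ids not in matrix: {missing}")
    if len(qc_ids) < 2:
        raise ValueError("need >= 2 QC replicates to compute CV")
    if rules is None:
        rules = DeisotopeRules()

    n_input = matrix.n_features
    qc_areas = matrix.values.loc[qc_ids].to_numpy()

    cv = np.array([_qc_cv(qc_areas[:, j]) for j in range(n_input)])
    keep1 = cv <= cv_max
    removed_cv = int((~keep1).sum())

    snr = matrix.feature_meta["snr"].to_numpy()
    snr_skipped = bool(np.isnan(snr).all())
    if snr_skipped:
        logger.warning("no S/N column supplied; skipping the S/N filter step")
        keep2 = keep1
        removed_snr = 0
    else:
        keep2 = keep1 & (np.nan_to_num(snr, nan=np.inf) >= snr_min)
        removed_snr = int(keep1.sum() - keep2.sum())

    sub = FeatureMatrix(
        values=matrix.values.loc[:, keep2],
        feature_meta=matrix.feature_meta.loc[keep2],
        stage="raw",
        roles=matrix.roles,
        run_order=matrix.run_order,
    )
    ref_area = sub.values.loc[qc_ids].to_numpy().mean(axis=0)
    flagged = _flag_ions(sub, rules, ref_area)
    removed_ions = int(flagged.sum())

    out = FeatureMatrix(
        values=sub.values.loc[:, ~flagged],
        feature_meta=sub.feature_meta.loc[~flagged],
        stage="filtered",
        roles=matrix.roles,
        run_order=matrix.run_order,
    )
    report = FilterReport(
        n_input=n_input,
        removed_cv=removed_cv,
        removed_snr=removed_snr,
        removed_ions=removed_ions,
        n_output=out.n_features,
        snr_skipped=snr_skipped,
    )
    return out, report


# ---------------------------------------------------------------------------
# QC-pool normalization
# ---------------------------------------------------------------------------

def _bracket_qcs(
    sample_pos: float, qc_pos: np.ndarray, qc_ids: list[str]
) -> list[str]:
    """QC injections bracketing a sample in run order (nearest before + after)."""
    before = qc_pos[qc_pos <= sample_pos]
    after = qc_pos[qc_pos >= sample_pos]
    chosen = []
    if len(before):
        chosen.append(before.max())
    if len(after):
        chosen.append(after.min())
    return [qc_ids[int(np.where(qc_pos == p)[0][0])] for p in dict.fromkeys(chosen)]


def qc_normalize(matrix: FeatureMatrix, qc_ids: Sequence[str]) -> FeatureMatrix:
    """Express each patient sample as the ratio to its bracketing QC-pool mean.

    When run order is known, each sample is divided feature-wise by the mean
    area of the nearest preceding and following QC injections (the bracketing
    pair); without run order, by the mean over all QC replicates. QC rows are
    dropped from the output. Features whose QC mean is zero in any bracket
    cannot be ratioed and are dropped with a warning.
    """
    qc_ids = list(qc_ids)
    missing = [q for q in qc_ids if q not in matrix.values.index]
    if missing:
        raise ValueError(f"QC ids not in matrix: {missing}")
    patients = [s for s in matrix.values.index if s not in set(qc_ids)]

    qc_vals = matrix.values.loc[qc_ids]
    if matrix.run_order is not None and all(q in matrix.run_order.index for q in qc_ids):
        qc_pos = matrix.run_order.loc[qc_ids].to_numpy(dtype=float)
        denom = {}
        for s in patients:
            pos = float(matrix.run_order.loc[s])
            bracket = _bracket_qcs(pos, qc_pos, qc_ids)
            denom[s] = qc_vals.loc[bracket].mean(axis=0)
        denom_df = pd.DataFrame(denom).T.loc[patients]
    else:
        denom_df = pd.DataFrame(
            np.tile(qc_vals.mean(axis=0).to_numpy(), (len(patients), 1)),
            index=patients,
            columns=matrix.values.columns,
        )

    bad = (denom_df <= 0).any(axis=0)
    if bad.any():
        logger.warning("dropping %d features with zero QC mean in some bracket", int(bad.sum()))
    keep = ~bad
    ratios = matrix.values.loc[patients, keep.index[keep]] / denom_df.loc[:, keep.index[keep]]
    roles = matrix.roles.loc[patients] if matrix.roles is not None else None
    run_order = matrix.run_order.loc[patients] if matrix.run_order is not None else None
    return FeatureMatrix(
        values=ratios,
        feature_meta=matrix.feature_meta.loc[keep.index[keep]],
        stage="normalized",
        roles=roles,
        run_order=run_order,
    )
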
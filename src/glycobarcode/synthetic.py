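"""Synthetic cohort generator emulating the serum glycopeptide study design.

No patient data are deposited with the study this package reimplements, so a
generator produces cohorts with the statistical structure the pipeline
assumes: 97 early-stage EOC + 254 non-EOC samples, 1712 glycopeptide features
organized into correlated blocks (log-normal multiplicative noise on the
QC-ratio scale, block-factor correlation), a planted differentially expressed
feature subset concentrated in one block, and CA125/HE4 marker values drawn
log-normally with class separation calibrated to target single-marker
ROC-AUCs (0.86 and 0.87) through the binormal identity
AUC = Phi(delta / sqrt(sigma1^2 + sigma2^2)).

The generator also emits raw per-run peak tables (with QC-pool injections in
bracketing pairs around every block of ``qc_interval`` patient runs, position
jitter, and optional injected isotope/adduct/junk contamination) in exactly
the CSV formats the peaks module reads, so the alignment-filter-normalize
stage is testable end to end against known ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .peaks import ISOTOPE_SPACING, FeatureMatrix, Peak, PeakTable, feature_id

#: Chromatographic gradient window (minutes) and glycopeptide m/z range (Da)
#: within which consensus positions are drawn.
RT_RANGE = (1.0, 14.0)
MZ_RANGE = (800.0, 3000.0)


@dataclass
class CohortSpec:
    """Study-condition parameters of the synthetic cohort."""

    n_eoc: int = 97
    n_non: int = 254
    n_features: int = 1712
    n_blocks: int = 8
    block_corr: float = 0.7
    de_fraction: float = 0.05
    effect_size: float = 1.0  # mean log2 shift of DE features in EOC
    marker_auc_ca125: float = 0.86
    marker_auc_he4: float = 0.87
    noise_cv: float = 0.2
    scatter_de: bool = False  # spread DE features across blocks
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_eoc, self.n_non, self.n_features, self.n_blocks) <= 0:
            raise ValueError("counts must be positive")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must be in [0, 1]")
        for auc in (self.marker_auc_ca125, self.marker_auc_he4):
            if not 0.5 < auc < 1.0:
                raise ValueError(f"marker AUC target must be in (0.5, 1), got {auc}")
        if not 0 <= self.block_corr < 1:
            raise ValueError("block_corr must be in [0, 1)")


@dataclass
class SyntheticCohort:
    matrix: FeatureMatrix  # normalized QC-ratio scale
    markers: pd.DataFrame  # columns ca125, he4; index sample_id
    labels: pd.Series  # "EOC" / "non-EOC"
    de_features: list[str]
    blocks: pd.Series  # feature_id -> block index
    spec: CohortSpec

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels.index)


#: Log-scale location and spread of the marker distributions in the non-EOC
#: class: CA125 median 13 U/mL, HE4 median 45 pmol/L, typical of healthy sera.
MARKER_BASE = {"ca125": (np.log(13.0), 0.7), "he4": (np.log(45.0), 0.35)}


def _marker_values(
    rng: np.random.Generator, n_eoc: int, n_non: int, target_auc: float, mu0: float, sigma: float
) -> np.ndarray:
    """Log-normal marker draws; EOC mean shifted to hit the target binormal AUC."""
    delta = stats.norm.ppf(target_auc) * sigma * np.sqrt(2.0)
    eoc = rng.normal(mu0 + delta, sigma, n_eoc)
    non = rng.normal(mu0, sigma, n_non)
    return np.exp(np.concatenate([eoc, non]))


def generate_cohort(spec: CohortSpec | None = None) -> SyntheticCohort:
    """Draw a fully reproducible synthetic cohort on the QC-ratio scale.

    Per-sample feature values are ``exp(a * z_block + b * eps)`` rescaled to
    unit mean in the non-EOC class, where ``z_block`` is a per-sample latent
    factor shared by all features of a block, giving within-block log-scale
    correlation ``block_corr``; ``b`` is set so the idiosyncratic
    multiplicative noise has coefficient of variation ``noise_cv``.
    Differentially expressed features are multiplied by ``2**effect_size`` in
    EOC samples.
    """
    if spec is None:
        spec = CohortSpec()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_eoc + spec.n_non
    labels = np.array(["EOC"] * spec.n_eoc + ["non-EOC"] * spec.n_non)
    sample_ids = [
        f"{'EOC' if l == 'EOC' else 'NON'}_{i + 1:04d}" for i, l in enumerate(labels)
    ]

    # feature consensus positions and block membership
    rt = rng.uniform(*RT_RANGE, spec.n_features)
    mz = rng.uniform(*MZ_RANGE, spec.n_features)
    fids = [feature_id(r, m) for r, m in zip(rt, mz)]
    blocks = np.arange(spec.n_features) * spec.n_blocks // spec.n_features

    b = np.sqrt(np.log1p(spec.noise_cv**2))  # idiosyncratic log-sd from CV
    rho = spec.block_corr
    a = b * np.sqrt(rho / (1.0 - rho)) if rho > 0 else 0.0

    z = rng.standard_normal((n, spec.n_blocks))
    eps = rng.standard_normal((n, spec.n_features))
    log_vals = a * z[:, blocks] + b * eps
    values = np.exp(log_vals - (a**2 + b**2) / 2.0)  # unit mean in non-EOC

    n_de = int(round(spec.de_fraction * spec.n_features))
    if spec.scatter_de:
        de_idx = rng.choice(spec.n_features, size=n_de, replace=False)
    else:
        # concentrate the planted signal in the leading block(s)
        de_idx = np.argsort(blocks, kind="stable")[:n_de]
    values[np.ix_(labels == "EOC", de_idx)] *= 2.0**spec.effect_size

    ca125 = _marker_values(
        rng, spec.n_eoc, spec.n_non, spec.marker_auc_ca125, *MARKER_BASE["ca125"]
    )
    he4 = _marker_values(
        rng, spec.n_eoc, spec.n_non, spec.marker_auc_he4, *MARKER_BASE["he4"]
    )

    meta = pd.DataFrame({"rt": rt, "mz": mz, "snr": np.nan}, index=fids)
    matrix = FeatureMatrix(
        values=pd.DataFrame(values, index=sample_ids, columns=fids),
        feature_meta=meta,
        stage="normalized",
        roles=pd.Series("patient", index=sample_ids),
    )
    return SyntheticCohort(
        matrix=matrix,
        markers=pd.DataFrame({"ca125": ca125, "he4": he4}, index=sample_ids),
        labels=pd.Series(labels, index=sample_ids, name="label"),
        de_features=[fids[i] for i in sorted(de_idx)],
        blocks=pd.Series(blocks, index=fids, name="block"),
        spec=spec,
    )


@dataclass
class ContaminationFlags:
    """How many contaminant features of each kind to inject into peak tables."""

    isotopes: int = 0
    adducts: int = 0
    high_cv: int = 0
    low_snr: int = 0

    def any(self) -> bool:
        return bool(self.isotopes or self.adducts or self.high_cv or self.low_snr)


@dataclass
class StudyGroundTruth:
    """Bookkeeping of what generate_peak_tables planted."""

    true_features: list[str]
    isotope_positions: list[tuple[float, float]] = field(default_factory=list)
    adduct_positions: list[tuple[float, float]] = field(default_factory=list)
    high_cv_positions: list[tuple[float, float]] = field(default_factory=list)
    low_snr_positions: list[tuple[float, float]] = field(default_factory=list)


def generate_peak_tables(
    cohort: SyntheticCohort,
    qc_interval: int = 20,
    jitter_rt: float = 0.1,
    jitter_mz: float = 0.01,
    contaminate: ContaminationFlags | None = None,
    qc_cv: float = 0.05,
    snr_range: tuple[float, float] = (10.0, 50.0),
    seed: int | None = None,
) -> tuple[list[PeakTable], pd.DataFrame, StudyGroundTruth]:
    """Materialize per-run peak tables from a cohort, plus manifest and truth.

    Patient areas are the cohort's QC-ratio values times a per-feature base
    intensity; QC-pool injections (base intensity with ``qc_cv`` replicate
    noise) bracket every block of ``qc_interval`` patient runs in pairs.
    Peak positions are jittered run-to-run (keep jitters below half the
    alignment tolerances). Optional contamination injects +1 isotopes and
    adducts of existing features (lower area, co-eluting), high-CV junk
    features, and low-S/N features, all recorded in the ground truth.
    """
    from .peaks import MZ_TOL, NEG_MODE_ADDUCTS, RT_TOL

    if jitter_rt >= RT_TOL / 2 or jitter_mz >= MZ_TOL / 2:
        raise ValueError("position jitter must stay below half the alignment tolerances")
    if contaminate is None:
        contaminate = ContaminationFlags()
    rng = np.random.default_rng(cohort.spec.seed + 1 if seed is None else seed)

    meta = cohort.matrix.feature_meta
    fids = list(meta.index)
    rt = meta["rt"].to_numpy()
    mz = meta["mz"].to_numpy()
    nf = len(fids)
    base = np.exp(rng.normal(np.log(1e5), 0.5, nf))
    snr_true = rng.uniform(*snr_range, nf)

    truth = StudyGroundTruth(true_features=fids)
    iso_parent = rng.choice(nf, size=min(contaminate.isotopes, nf), replace=False)
    add_parent = rng.choice(nf, size=min(contaminate.adducts, nf), replace=False)
    adduct_deltas = list(NEG_MODE_ADDUCTS.values())
    truth.isotope_positions = [(float(rt[p]), float(mz[p] + ISOTOPE_SPACING)) for p in iso_parent]
    truth.adduct_positions = [
        (float(rt[p]), float(mz[p] + adduct_deltas[i % len(adduct_deltas)]))
        for i, p in enumerate(add_parent)
    ]
    junk_rt = rng.uniform(*RT_RANGE, contaminate.high_cv)
    junk_mz = rng.uniform(*MZ_RANGE, contaminate.high_cv)
    truth.high_cv_positions = list(zip(junk_rt.tolist(), junk_mz.tolist()))
    weak_rt = rng.uniform(*RT_RANGE, contaminate.low_snr)
    weak_mz = rng.uniform(*MZ_RANGE, contaminate.low_snr)
    truth.low_snr_positions = list(zip(weak_rt.tolist(), weak_mz.tolist()))

    def make_table(sample_id: str, role: str, ratios: np.ndarray, is_qc: bool) -> PeakTable:
        areas = ratios * base
        peaks = [
            Peak(
                rt=float(max(0.0, rt[f] + rng.uniform(-jitter_rt, jitter_rt))),
                mz=float(mz[f] + rng.uniform(-jitter_mz, jitter_mz)),
                area=float(areas[f]),
                snr=float(snr_true[f]),
            )
            for f in range(nf)
        ]
        for i, p in enumerate(iso_parent):
            peaks.append(
                Peak(
                    rt=float(max(0.0, rt[p] + rng.uniform(-jitter_rt, jitter_rt))),
                    mz=float(mz[p] + ISOTOPE_SPACING + rng.uniform(-jitter_mz, jitter_mz)),
                    area=float(0.4 * areas[p]),
                    snr=float(snr_true[p]),
                )
            )
        for i, p in enumerate(add_parent):
            peaks.append(
                Peak(
                    rt=float(max(0.0, rt[p] + rng.uniform(-jitter_rt, jitter_rt))),
                    mz=float(
                        mz[p]
                        + adduct_deltas[i % len(adduct_deltas)]
                        + rng.uniform(-jitter_mz, jitter_mz)
                    ),
                    area=float(0.3 * areas[p]),
                    snr=float(snr_true[p]),
                )
            )
        for j in range(contaminate.high_cv):
            peaks.append(
                Peak(
                    rt=float(max(0.0, junk_rt[j] + rng.uniform(-jitter_rt, jitter_rt))),
                    mz=float(junk_mz[j] + rng.uniform(-jitter_mz, jitter_mz)),
                    area=float(np.exp(rng.normal(np.log(5e4), 1.5))),  # wild replicate scatter
                    snr=float(rng.uniform(*snr_range)),
                )
            )
        for j in range(contaminate.low_snr):
            peaks.append(
                Peak(
                    rt=float(max(0.0, weak_rt[j] + rng.uniform(-jitter_rt, jitter_rt))),
                    mz=float(weak_mz[j] + rng.uniform(-jitter_mz, jitter_mz)),
                    area=float(1e3 * np.exp(rng.normal(0, 0.1))),
                    snr=float(rng.uniform(1.0, 4.0)),
                )
            )
        return PeakTable(sample_id=sample_id, role=role, peaks=peaks)

    tables: list[PeakTable] = []
    manifest_rows: list[dict] = []
    qc_count = 0
    pos = 0
    patient_ids = cohort.sample_ids
    ratios = cohort.matrix.values.to_numpy()

    def add_qc() -> None:
        nonlocal qc_count, pos
        qc_count += 1
        sid = f"QC_{qc_count:03d}"
        qc_ratio = np.exp(rng.normal(0, np.sqrt(np.log1p(qc_cv**2)), nf))
        tables.append(make_table(sid, "qc", qc_ratio, is_qc=True))
        manifest_rows.append(
            {
                "sample_id": sid,
                "path": f"{sid}.csv",
                "role": "qc",
                "label": "",
                "ca125": "",
                "he4": "",
                "run_order": pos,
            }
        )
        pos += 1

    for start in range(0, len(patient_ids), qc_interval):
        batch = patient_ids[start : start + qc_interval]
        add_qc()
        for sid in batch:
            i = patient_ids.index(sid)
            tables.append(make_table(sid, "patient", ratios[i], is_qc=False))
            manifest_rows.append(
                {
                    "sample_id": sid,
                    "path": f"{sid}.csv",
                    "role": "patient",
                    "label": cohort.labels.loc[sid],
                    "ca125": float(cohort.markers.loc[sid, "ca125"]),
                    "he4": float(cohort.markers.loc[sid, "he4"]),
                    "run_order": pos,
                }
            )
            pos += 1
        add_qc()

    manifest = pd.DataFrame(manifest_rows)
    return tables, manifest, truth


def write_study(
    tables: list[PeakTable],
    manifest: pd.DataFrame,
    truth: StudyGroundTruth | None,
    outdir: str | Path,
) -> Path:
    """Write peak tables, manifest and ground truth as the CSV/JSON study layout."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for table in tables:
        df = pd.DataFrame(
            {
                "rt": [p.rt for p in table.peaks],
                "mz": [p.mz for p in table.peaks],
                "area": [p.area for p in table.peaks],
                "snr": [p.snr for p in table.peaks],
            }
        )
        df.to_csv(outdir / f"{table.sample_id}.csv", index=False)
    manifest_path = outdir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    if truth is not None:
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(asdict(truth), fh, indent=1)
    return manifest_path
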
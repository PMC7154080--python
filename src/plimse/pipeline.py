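"""End-to-end orchestration: simulate -> preprocess -> connectivity ->
complexity -> group statistics -> classification.

A run is fully determined by its :class:`RunConfig` (including the master
seed): regenerating with an identical config reproduces every output.  Each
stage writes tidy CSV tables; the run report is a JSON summary carrying the
config hash and seed for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .classify import ClassifierConfig, ClassifierReport, svm_cv
from .complexity import MSEParams, mse_curve, small_scale_mean
from .connectivity import hilbert_phase, node_degree, pli_matrix
from .preprocess import bandpass, segment_epochs, trim_edges
from .recording import BAND_NAMES, CANONICAL_BANDS, Recording, get_band
from .stats import DEFAULT_Q_LEVELS, AnovaResult, StatGrid, corr_grid, posthoc_map, rm_anova_mixed
from .synthetic import AD, HC, CohortConfig, SubjectLabel, generate_cohort

log = logging.getLogger("plimse")

CLASSIFIED_BANDS = ("alpha", "beta", "gamma")


@dataclass
class RunConfig:
    """Complete configuration of one pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    trim_samples: int = 1000
    epoch_length_s: float = 5.0
    bands: tuple[str, ...] = BAND_NAMES
    mse: MSEParams = field(default_factory=MSEParams)
    q_levels: tuple[float, ...] = DEFAULT_Q_LEVELS
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    write_recordings: bool = False
    recording_format: str = "csv"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bands"] = list(self.bands)
        d["q_levels"] = list(self.q_levels)
        d["mse"]["scales"] = list(self.mse.scales)
        d["cohort"]["lag_range"] = list(self.cohort.lag_range)
        return d

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


_SCHEMA = {
    "cohort": {"n_hc", "n_ad", "n_channels", "fs", "duration_s", "coupling",
               "noise_exponent", "band_amplitudes", "noise_amplitude",
               "lag_range", "master_seed"},
    "preprocess": {"trim_samples", "epoch_length_s", "bands"},
    "mse": {"m", "r_mode", "r_value", "scales"},
    "stats": {"q_levels"},
    "classifier": {"variance_threshold", "n_folds", "svm_c", "pca_scope", "seed"},
    "output": {"write_recordings", "recording_format"},
}


def validate_config(path: str | Path | None = None,
                    data: dict | None = None) -> RunConfig:
    """Build a fully defaulted RunConfig from a YAML file; unknown keys are errors."""
    if data is None:
        data = {}
        if path is not None:
            text = Path(path).read_text()
            data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping of sections")
    unknown_sections = set(data) - set(_SCHEMA)
    if unknown_sections:
        raise ValueError(f"unknown config sections: {sorted(unknown_sections)}")
    for section, keys in _SCHEMA.items():
        extra = set(data.get(section, {}) or {}) - keys
        if extra:
            raise ValueError(f"unknown keys in [{section}]: {sorted(extra)}")

    cohort_kwargs = dict(data.get("cohort", {}) or {})
    if "lag_range" in cohort_kwargs:
        cohort_kwargs["lag_range"] = tuple(cohort_kwargs["lag_range"])
    cohort = CohortConfig(**cohort_kwargs)
    pre = data.get("preprocess", {}) or {}
    for name in pre.get("bands", []):
        get_band(name).validate_against_fs(cohort.fs)
    mse_kwargs = dict(data.get("mse", {}) or {})
    if "scales" in mse_kwargs:
        mse_kwargs["scales"] = tuple(mse_kwargs["scales"])
    classifier = ClassifierConfig(**(data.get("classifier", {}) or {}))
    out = data.get("output", {}) or {}
    return RunConfig(
        cohort=cohort,
        trim_samples=int(pre.get("trim_samples", 1000)),
        epoch_length_s=float(pre.get("epoch_length_s", 5.0)),
        bands=tuple(pre.get("bands", BAND_NAMES)),
        mse=MSEParams(**mse_kwargs),
        q_levels=tuple((data.get("stats", {}) or {}).get("q_levels", DEFAULT_Q_LEVELS)),
        classifier=classifier,
        write_recordings=bool(out.get("write_recordings", False)),
        recording_format=str(out.get("recording_format", "csv")),
    )


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

@dataclass
class CohortFeatures:
    """Per-subject connectivity and complexity features of one cohort.

    ``pli`` is (subjects, bands, channels, channels); ``nd`` is
    (subjects, bands, channels); ``sampen`` is (subjects, channels, scales).
    """

    subject_ids: list[str]
    groups: np.ndarray
    channel_labels: tuple[str, ...]
    band_names: tuple[str, ...]
    scales: tuple[int, ...]
    pli: np.ndarray
    nd: np.ndarray
    sampen: np.ndarray

    @property
    def pair_labels(self) -> list[str]:
        return [f"{a}-{b}" for a, b in combinations(self.channel_labels, 2)]

    def pli_pairs(self) -> np.ndarray:
        """Upper-triangle PLI values, shape (subjects, n_pairs, bands)."""
        k = len(self.channel_labels)
        iu = np.triu_indices(k, 1)
        return self.pli[:, :, iu[0], iu[1]].transpose(0, 2, 1)

    def small_scale_sampen(self, lo: int = 1, hi: int = 5) -> np.ndarray:
        idx = [self.scales.index(s) for s in range(lo, hi + 1)]
        return self.sampen[:, :, idx].mean(axis=2)


def extract_subject_features(rec: Recording, config: RunConfig
                             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(pli[band, K, K], nd[band, K], sampen[K, scales]) for one subject."""
    core = trim_edges(rec, config.trim_samples)
    k = core.n_channels
    pli_out = np.zeros((len(config.bands), k, k))
    nd_out = np.zeros((len(config.bands), k))
    for bi, band_name in enumerate(config.bands):
        band_rec = bandpass(core, get_band(band_name))
        epochs = segment_epochs(band_rec, config.epoch_length_s,
                                band=get_band(band_name))
        mat = pli_matrix(hilbert_phase(epochs))
        pli_out[bi] = mat.values
        nd_out[bi] = node_degree(mat)
    curve = mse_curve(core, config.mse)
    return pli_out, nd_out, curve.values


def extract_cohort_features(cohort: list[tuple[Recording, SubjectLabel]],
                            config: RunConfig) -> CohortFeatures:
    recs = [r for r, _ in cohort]
    labels = [l for _, l in cohort]
    k = recs[0].n_channels
    n = len(recs)
    pli = np.zeros((n, len(config.bands), k, k))
    nd = np.zeros((n, len(config.bands), k))
    sampen = np.zeros((n, k, len(config.mse.scales)))
    for i, rec in enumerate(recs):
        pli[i], nd[i], sampen[i] = extract_subject_features(rec, config)
        log.info("features: subject %s done (%d/%d)", labels[i].subject_id, i + 1, n)
    return CohortFeatures(
        subject_ids=[l.subject_id for l in labels],
        groups=np.array([l.group for l in labels]),
        channel_labels=recs[0].channel_labels,
        band_names=tuple(config.bands),
        scales=tuple(config.mse.scales),
        pli=pli, nd=nd, sampen=sampen,
    )


# ---------------------------------------------------------------------------
# Group analyses on extracted features
# ---------------------------------------------------------------------------

def nd_anova_tables(feats: CohortFeatures) -> dict[str, AnovaResult]:
    """Per-band mixed ANOVA of node degree: group (between) x electrode (within)."""
    out = {}
    for bi, band in enumerate(feats.band_names):
        rows = []
        for si, sid in enumerate(feats.subject_ids):
            for ci, ch in enumerate(feats.channel_labels):
                rows.append({"subject": sid, "group": feats.groups[si],
                             "electrode": ch, "nd": feats.nd[si, bi, ci]})
        out[band] = rm_anova_mixed(pd.DataFrame(rows), dv="nd", subject="subject",
                                   between="group", within=["electrode"])
    return out


def sampen_anova_table(feats: CohortFeatures) -> AnovaResult:
    """Mixed ANOVA of SampEn: group x electrode x temporal scale."""
    n, k, s = feats.sampen.shape
    sid = np.repeat(feats.subject_ids, k * s)
    grp = np.repeat(feats.groups, k * s)
    elec = np.tile(np.repeat(feats.channel_labels, s), n)
    scale = np.tile(list(feats.scales), n * k)
    df = pd.DataFrame({"subject": sid, "group": grp, "electrode": elec,
                       "scale": scale, "sampen": feats.sampen.reshape(-1)})
    return rm_anova_mixed(df, dv="sampen", subject="subject", between="group",
                          within=["electrode", "scale"])


def group_stat_grids(feats: CohortFeatures,
                     q_levels: tuple[float, ...] = DEFAULT_Q_LEVELS
                     ) -> dict[str, StatGrid]:
    """The three post-hoc t-maps (PLI pairs, ND, SampEn) with pooled BH-FDR."""
    grids = {
        "pli_pairs": posthoc_map(
            feats.pli_pairs(), feats.groups,
            layout={"pair": feats.pair_labels, "band": list(feats.band_names)},
            q_levels=q_levels),
        "nd": posthoc_map(
            feats.nd.transpose(0, 2, 1), feats.groups,
            layout={"electrode": list(feats.channel_labels),
                    "band": list(feats.band_names)},
            q_levels=q_levels),
        "sampen": posthoc_map(
            feats.sampen, feats.groups,
            layout={"electrode": list(feats.channel_labels),
                    "scale": list(feats.scales)},
            q_levels=q_levels),
    }
    return grids


def correlation_grids(feats: CohortFeatures,
                      q_levels: tuple[float, ...] = DEFAULT_Q_LEVELS
                      ) -> dict[str, StatGrid]:
    """Per-group SampEn-vs-ND Pearson grids (electrode x band x scale)."""
    out = {}
    for group in (HC, AD):
        sel = feats.groups == group
        if sel.sum() < 3:
            continue
        out[group] = corr_grid(
            feats.sampen[sel], feats.nd[sel],
            electrode_labels=list(feats.channel_labels),
            band_labels=list(feats.band_names),
            scale_labels=list(feats.scales),
            q_levels=q_levels)
    return out


def classification_reports(feats: CohortFeatures, config: ClassifierConfig
                           ) -> dict[str, ClassifierReport]:
    """Linear-SVM reports for per-band ND features and small-scale mean SampEn."""
    y = (feats.groups == AD).astype(int)
    reports = {}
    for band in CLASSIFIED_BANDS:
        if band not in feats.band_names:
            continue
        bi = feats.band_names.index(band)
        reports[f"nd_{band}"] = svm_cv(feats.nd[:, bi, :], y, config,
                                       feature_set=f"nd_{band}")
    reports["sampen_1_5"] = svm_cv(feats.small_scale_sampen(), y, config,
                                   feature_set="sampen_1_5")
    return reports


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

@dataclass
class RunReport:
    config_hash: str
    seed: int
    output_dir: Path
    anova: dict
    grid_summaries: dict
    classifiers: dict
    paths: dict


def _grid_summary(grid: StatGrid, q_levels) -> dict:
    return {
        "n_tests": grid.n_tests,
        "n_excluded": grid.n_excluded,
        **{f"n_significant_q{q:g}": int(grid.masks[q].sum()) for q in q_levels},
        **{f"realized_p_threshold_q{q:g}": grid.thresholds[q] for q in q_levels},
    }


def run_all(config: RunConfig, out_dir: str | Path) -> RunReport:
    """Execute every stage on a freshly simulated cohort and write all outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    probe = out_dir / ".write_probe"
    try:
        probe.write_text("ok")
        probe.unlink()
    except OSError as exc:
        raise RuntimeError(f"output directory {out_dir} is not writable: {exc}")

    chash = config.config_hash()
    seed = config.cohort.master_seed
    log.info("run %s: simulating cohort (%d HC, %d AD)", chash,
             config.cohort.n_hc, config.cohort.n_ad)
    cohort = generate_cohort(config.cohort)

    paths: dict[str, str] = {}
    if config.write_recordings:
        rec_dir = out_dir / "recordings"
        rec_dir.mkdir(exist_ok=True)
        manifest = []
        for rec, lbl in cohort:
            fname = f"{lbl.subject_id}.{config.recording_format}"
            rio.write_recording(rec, rec_dir / fname, config.recording_format)
            manifest.append({"subject_id": lbl.subject_id, "group": lbl.group,
                             "seed": lbl.seed, "file": f"recordings/{fname}"})
        rio.write_manifest(manifest, out_dir / "manifest.csv")
        paths["manifest"] = "manifest.csv"

    feats = extract_cohort_features(cohort, config)

    nd_rows = []
    for si, sid in enumerate(feats.subject_ids):
        for bi, band in enumerate(feats.band_names):
            for ci, ch in enumerate(feats.channel_labels):
                nd_rows.append({"subject": sid, "group": feats.groups[si],
                                "band": band, "electrode": ch,
                                "nd": feats.nd[si, bi, ci]})
    pd.DataFrame(nd_rows).to_csv(out_dir / "node_degree.csv", index=False)
    paths["node_degree"] = "node_degree.csv"

    mse_rows = []
    for si, sid in enumerate(feats.subject_ids):
        for ci, ch in enumerate(feats.channel_labels):
            for ki, s in enumerate(feats.scales):
                v = feats.sampen[si, ci, ki]
                mse_rows.append({"subject": sid, "group": feats.groups[si],
                                 "channel": ch, "scale": s, "sampen": v,
                                 "defined": bool(np.isfinite(v))})
    pd.DataFrame(mse_rows).to_csv(out_dir / "mse.csv", index=False)
    paths["mse"] = "mse.csv"

    anova = {band: res for band, res in nd_anova_tables(feats).items()}
    anova["sampen"] = sampen_anova_table(feats)
    anova_json = {}
    for name, res in anova.items():
        anova_json[name] = res.table.to_dict(orient="records")
        res.table.to_csv(out_dir / f"anova_{name}.csv", index=False)
        paths[f"anova_{name}"] = f"anova_{name}.csv"

    grids = group_stat_grids(feats, config.q_levels)
    grids.update({f"corr_{g}": grid
                  for g, grid in correlation_grids(feats, config.q_levels).items()})
    grid_summaries = {}
    for name, grid in grids.items():
        grid.to_frame().to_csv(out_dir / f"grid_{name}.csv", index=False)
        paths[f"grid_{name}"] = f"grid_{name}.csv"
        grid_summaries[name] = _grid_summary(grid, config.q_levels)
        log.info("grid %s: %s", name, grid_summaries[name])

    reports = classification_reports(feats, config.classifier)
    classifiers = {name: rep.to_dict() for name, rep in reports.items()}
    roc_rows = []
    for name, rep in reports.items():
        for f, t in zip(rep.roc_fpr, rep.roc_tpr):
            roc_rows.append({"feature_set": name, "fpr": f, "tpr": t})
    pd.DataFrame(roc_rows).to_csv(out_dir / "roc_curves.csv", index=False)
    paths["roc_curves"] = "roc_curves.csv"

    report = RunReport(config_hash=chash, seed=seed, output_dir=out_dir,
                       anova=anova_json, grid_summaries=grid_summaries,
                       classifiers=classifiers, paths=paths)
    report_json = {
        "config_hash": chash,
        "seed": seed,
        "config": config.to_dict(),
        "anova": anova_json,
        "grid_summaries": grid_summaries,
        "classifiers": classifiers,
        "paths": paths,
    }
    (out_dir / "run_report.json").write_text(json.dumps(report_json, indent=2))
    return report
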
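"""End-to-end orchestration of the diagnostic-index workflow.

Flow: simulate (or ingest) a cohort -> extract the biomarker battery for
every recording -> map group differences on the training visit (visit 2)
with the binomial channel correction -> reduce to median-over-significant-
channel features -> select biomarkers (genetic search, elastic net, or a
single named biomarker) and fit the logistic index on the training visit
-> predict the evaluation visit (visit 1), separately for all subjects and
for the held-out subjects that lack a training-visit recording -> optional
half-split cross-validation. Also: recording container I/O (HDF5, EDF
read) and a machine-readable report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, statmap
from .biomarkers import BiomarkerDef, BiomarkerTensor, default_registry, extract_battery
from .signal_core import InvalidArgumentError, Recording
from .synthcohort import CohortSpec, generate_cohort

log = logging.getLogger("eegdx.pipeline")


# ---------------------------------------------------------------------------
# Recording container I/O
# ---------------------------------------------------------------------------

def write_recording(rec: Recording, path) -> None:
    """Write a recording to the repository HDF5 container."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f.attrs["sampling_rate"] = rec.sampling_rate
        f.attrs["channel_labels"] = [str(c) for c in rec.channel_labels]
        f.attrs["subject_id"] = rec.subject_id
        f.attrs["visit"] = rec.visit
        f.attrs["group"] = rec.group


def read_recording(path, fmt: str | None = None) -> Recording:
    """Read a recording from the repository container or an EDF file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "h5"
    if fmt == "edf":
        return _read_edf(path)
    import h5py

    with h5py.File(path, "r") as f:
        for key in ("sampling_rate", "channel_labels"):
            if key not in f.attrs:
                raise InvalidArgumentError(f"malformed header: missing '{key}'")
        data = f["data"][()]
        if not np.all(np.isfinite(data)):
            raise InvalidArgumentError("non-finite data samples")
        return Recording(
            data=data, sampling_rate=float(f.attrs["sampling_rate"]),
            channel_labels=[str(c) for c in f.attrs["channel_labels"]],
            subject_id=str(f.attrs.get("subject_id", "")),
            visit=int(f.attrs.get("visit", 1)),
            group=str(f.attrs.get("group", "unknown")))


def _read_edf(path: Path) -> Recording:
    try:
        import mne
    except ImportError as e:  # pragma: no cover
        raise InvalidArgumentError("EDF support requires mne") from e
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    if not np.all(np.isfinite(data)):
        raise InvalidArgumentError("non-finite data samples in EDF")
    return Recording(data=data, sampling_rate=float(raw.info["sfreq"]),
                     channel_labels=list(raw.ch_names))


# ---------------------------------------------------------------------------
# Config and report
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything needed to run and reproduce the full workflow."""

    cohort: CohortSpec | None = None
    recording_dir: str | None = None
    registry: list[BiomarkerDef] | None = None
    training_visit: int = 2
    evaluation_visit: int = 1
    selection_method: str = "genetic"  # genetic | elastic_net | single:<name>
    genetic: classify.GeneticSearchConfig | None = None
    elastic_net: classify.ElasticNetConfig | None = None
    alpha: float = 0.05
    k_min: int = 3
    run_half_split: bool = True
    half_split_iterations: int = 1000
    reselect_in_half_split: bool = False
    master_seed: int = 0
    positive_group: str = "AD-converter"

    def __post_init__(self) -> None:
        if self.training_visit == self.evaluation_visit:
            raise InvalidArgumentError("training visit must differ from evaluation visit")

    def hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return {k: enc(v) for k, v in dataclasses.asdict(o).items()}
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (list, tuple)):
                return [enc(v) for v in o]
            if isinstance(o, dict):
                return {str(k): enc(v) for k, v in o.items()}
            return repr(o)

        blob = json.dumps(enc(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class EvaluationReport:
    """All outcome metrics plus the provenance needed to reproduce them."""

    selected_biomarkers: list[str]
    coefficients: dict
    training_metrics: dict
    evaluation_metrics: dict
    heldout_metrics: dict | None
    half_split_metrics: dict | None
    difference_map_summary: dict
    training_subjects: list[str]
    heldout_subjects: list[str]
    criterion_trace: list[float] | None
    config_hash: str = ""
    master_seed: int = 0

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (np.floating, np.integer)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(type(o))

        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True,
                          default=default)


def write_report(report: EvaluationReport, out_dir) -> Path:
    """Write the machine-readable report and a short human summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report.to_json())
    lines = [
        f"diagnostic index: {len(report.selected_biomarkers)} biomarkers",
        *[f"  {n}: {report.coefficients.get(n, float('nan')):+.3f}"
          for n in report.selected_biomarkers],
        f"training-visit metrics:   {_fmt(report.training_metrics)}",
        f"evaluation-visit metrics: {_fmt(report.evaluation_metrics)}",
    ]
    if report.heldout_metrics:
        lines.append(f"held-out-only metrics:    {_fmt(report.heldout_metrics)}")
    if report.half_split_metrics:
        lines.append(f"half-split CV medians:    {_fmt(report.half_split_metrics)}")
    lines.append(f"config {report.config_hash}  seed {report.master_seed}")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    return out / "report.json"


def read_report(path) -> EvaluationReport:
    d = json.loads(Path(path).read_text())
    return EvaluationReport(**d)


def _fmt(m: dict) -> str:
    keys = ("SE", "SP", "PPV", "MCC", "PLR")
    return "  ".join(f"{k}={m[k]:.2f}" for k in keys if k in m)


# ---------------------------------------------------------------------------
# The pipeline
# ---------------------------------------------------------------------------

def _load_directory(recording_dir: str) -> tuple[dict, pd.DataFrame]:
    """Ingest a directory of container files + subjects.tsv."""
    d = Path(recording_dir)
    subjects = pd.read_csv(d / "subjects.tsv", sep="\t")
    recordings = {}
    for _, row in subjects.iterrows():
        for visit, col in ((1, "visit1_file"), (2, "visit2_file")):
            fname = row.get(col)
            if isinstance(fname, str) and fname:
                rec = read_recording(d / fname)
                rec.subject_id, rec.visit, rec.group = (
                    row["subject_id"], visit, row["group"])
                recordings[(row["subject_id"], visit)] = rec
    if "has_visit2" not in subjects.columns:
        subjects["has_visit2"] = [
            (sid, 2) in recordings for sid in subjects["subject_id"]]
    return recordings, subjects


def run_pipeline(config: PipelineConfig) -> EvaluationReport:
    """Execute the full train-on-visit-2 / predict-visit-1 workflow."""
    t0 = time.time()
    if config.cohort is not None:
        recordings, subjects = generate_cohort(config.cohort)
    elif config.recording_dir is not None:
        recordings, subjects = _load_directory(config.recording_dir)
    else:
        raise InvalidArgumentError("config needs a cohort spec or recording dir")
    registry = config.registry or default_registry()
    log.info("stage=ingest n_recordings=%d t=%.1fs", len(recordings),
             time.time() - t0)

    tensors = {key: extract_battery(rec, registry)
               for key, rec in recordings.items()}
    log.info("stage=extract n_biomarkers=%d t=%.1fs", len(registry),
             time.time() - t0)

    groups = sorted(subjects["group"].unique())
    if len(groups) != 2:
        raise InvalidArgumentError("need exactly two groups")
    pos = config.positive_group
    neg = [g for g in groups if g != pos][0]

    tv, ev = config.training_visit, config.evaluation_visit
    train_subjects = subjects.loc[subjects["has_visit2"], "subject_id"].tolist() \
        if tv == 2 else subjects["subject_id"].tolist()
    heldout = [s for s in subjects["subject_id"] if s not in train_subjects]

    def tensors_for(subject_ids, visit):
        return [tensors[(s, visit)] for s in subject_ids
                if (s, visit) in tensors]

    group_of = dict(zip(subjects["subject_id"], subjects["group"]))
    train_neg = [s for s in train_subjects if group_of[s] == neg]
    train_pos = [s for s in train_subjects if group_of[s] == pos]
    dmap = statmap.difference_map(tensors_for(train_neg, tv),
                                  tensors_for(train_pos, tv),
                                  alpha=config.alpha, k_min=config.k_min)
    n_selected = int(dmap.corrected_significant.sum())
    log.info("stage=difference_map corrected_significant=%d t=%.1fs",
             n_selected, time.time() - t0)

    def feature_table(subject_ids, visit) -> pd.DataFrame:
        tab = statmap.reduce_to_features(tensors_for(subject_ids, visit), dmap)
        tab["label"] = (tab["group"] == pos).astype(int)
        return tab

    feat_cols = dmap.selected_biomarkers()
    train_tab = feature_table(train_subjects, tv)
    eval_tab = feature_table(subjects["subject_id"].tolist(), ev)

    # drop features not estimable on every training subject
    feat_cols = [c for c in feat_cols
                 if np.all(np.isfinite(train_tab[c]))
                 and np.all(np.isfinite(eval_tab[c]))]

    report_kwargs: dict = dict(
        difference_map_summary={
            "n_biomarkers": len(dmap.biomarker_names),
            "n_corrected_significant": n_selected,
            "selected": feat_cols},
        training_subjects=train_subjects, heldout_subjects=heldout,
        criterion_trace=None, config_hash=config.hash(),
        master_seed=config.master_seed)

    y_train = train_tab["label"].to_numpy()
    if not feat_cols or np.unique(y_train).size < 2:
        # degenerate: nothing survives the correction -> no model; predict
        # the majority training class everywhere
        majority = int(y_train.mean() >= 0.5) if y_train.size else 0
        y_eval = eval_tab["label"].to_numpy()
        cls = np.full(y_eval.size, majority)
        em = classify.outcome_metrics(cls, y_eval).as_dict()
        hm = None
        if heldout:
            hmask = eval_tab["subject_id"].isin(heldout).to_numpy()
            if np.unique(y_eval[hmask]).size == 2:
                hm = classify.outcome_metrics(cls[hmask], y_eval[hmask]).as_dict()
        return EvaluationReport(
            selected_biomarkers=[], coefficients={},
            training_metrics={}, evaluation_metrics=em, heldout_metrics=hm,
            half_split_metrics=None, **report_kwargs)

    X_train = train_tab[feat_cols]
    method = config.selection_method
    trace = None
    if method == "genetic":
        gcfg = config.genetic or classify.GeneticSearchConfig(
            seed=config.master_seed)
        gcfg = dataclasses.replace(
            gcfg, seed_set_size=min(gcfg.seed_set_size, len(feat_cols)))
        selected, model, trace = classify.genetic_search(X_train, y_train, gcfg)
    elif method == "elastic_net":
        ecfg = config.elastic_net or classify.ElasticNetConfig(
            seed=config.master_seed)
        selected, model = classify.fit_elastic_net(X_train, y_train, ecfg)
    elif method.startswith("single:"):
        name = method.split(":", 1)[1]
        if name not in feat_cols:
            raise InvalidArgumentError(
                f"biomarker '{name}' not among corrected-significant features")
        selected = [name]
        model = classify.fit_logistic(X_train[[name]], y_train)
    else:
        raise InvalidArgumentError(f"unknown selection method '{method}'")
    log.info("stage=selection method=%s k=%d t=%.1fs", method, len(selected),
             time.time() - t0)

    def evaluate(tab: pd.DataFrame) -> dict:
        _, cls = classify.predict(model, tab)
        return classify.outcome_metrics(cls, tab["label"].to_numpy()).as_dict()

    training_metrics = evaluate(train_tab)
    evaluation_metrics = evaluate(eval_tab)
    heldout_metrics = None
    if heldout:
        htab = eval_tab[eval_tab["subject_id"].isin(heldout)]
        if htab["label"].nunique() == 2:
            heldout_metrics = evaluate(htab)

    half_split = None
    if config.run_half_split:
        if config.reselect_in_half_split and method == "genetic":
            gcfg_hs = dataclasses.replace(
                config.genetic or classify.GeneticSearchConfig(),
                seed=config.master_seed)

            def train_fn(f, l):
                _, m, _ = classify.genetic_search(f, l, gcfg_hs)
                return m
            hs_feats = train_tab[feat_cols]
        else:
            # reuse the fixed selected set; refit coefficients per split
            train_fn = lambda f, l: classify.fit_logistic(f, l)
            hs_feats = train_tab[selected] if selected else train_tab[feat_cols]
        try:
            half_split = classify.half_split_cv(
                hs_feats, y_train, train_fn=train_fn,
                n_iterations=config.half_split_iterations,
                seed=config.master_seed)
        except InvalidArgumentError:
            half_split = None
    log.info("stage=done t=%.1fs", time.time() - t0)

    report_kwargs["criterion_trace"] = trace
    return EvaluationReport(
        selected_biomarkers=list(selected),
        coefficients={n: float(b) for n, b in
                      zip(model.biomarker_names, model.betas)},
        training_metrics=training_metrics,
        evaluation_metrics=evaluation_metrics,
        heldout_metrics=heldout_metrics,
        half_split_metrics=half_split,
        **report_kwargs)
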
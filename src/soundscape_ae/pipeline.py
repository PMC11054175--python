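"""End-to-end pipeline orchestration.

Runs the full chain — synthesize (or point at) a corpus, segment and
screen recordings, compute spectrograms, train the autoencoder, embed,
project, cluster with a K sweep, decode prototypes and diel histograms,
and optionally run the cover-type classification baseline — from a single
validated configuration.  Every stage writes its artifacts under the run
directory; a machine-readable ``summary.json`` lists each artifact with a
content checksum, so a fixed config and seed can be verified to reproduce
a run bit-for-bit.

Completed stages are cached: each stage records a hash of its effective
configuration and input checksums, and is skipped on re-run when the hash
matches and its outputs are present.  Stage randomness fans out from the
global seed as ``seed + stage_index`` so stages stay independent.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import cae as cae_mod
from . import cluster as cluster_mod
from . import ingest as ingest_mod
from . import interpret as interpret_mod
from . import project as project_mod
from . import spectro as spectro_mod
from . import supervised as supervised_mod
from .synth import SoundComponent, SpecValidationError, SyntheticCorpusSpec, generate_corpus

__all__ = [
    "PipelineConfig",
    "SynthStage",
    "IngestStage",
    "ProjectStage",
    "ClusterStage",
    "ClassifyStage",
    "RunResult",
    "run_pipeline",
    "load_config",
    "artifact_checksum",
]

logger = logging.getLogger(__name__)

STAGE_ORDER = ["synth", "spectro", "train", "embed", "project", "cluster", "interpret", "classify"]


def _default_components() -> Tuple[SoundComponent, ...]:
    """A diel-structured soundscape: nocturnal anuran chorus, dawn bird
    activity, daytime insect band — disjoint spectral niches."""
    return (
        SoundComponent(kind="anuran_pulses", center_freq=2_000, bandwidth=400, amplitude=0.5,
                       pulse_rate=4.0, active_hours=frozenset([18, 19, 20, 21, 22, 23, 0, 1, 2, 3, 4, 5])),
        SoundComponent(kind="bird_chirp", center_freq=4_750, bandwidth=2_500, amplitude=0.5,
                       pulse_rate=2.0, active_hours=frozenset([6, 7, 8, 9, 10, 11])),
        SoundComponent(kind="insect_band", center_freq=6_000, bandwidth=1_000, amplitude=0.5,
                       active_hours=frozenset([12, 13, 14, 15, 16, 17])),
    )


@dataclass(frozen=True)
class SynthStage:
    """Corpus source: synthesize with these parameters, or read ``input_dir``."""

    input_dir: Optional[str] = None
    n_recorders: int = 2
    n_days: int = 1
    recordings_per_hour: int = 1
    duration_s: float = 60.0
    sample_rate: int = 22_050
    noise_floor: float = 0.001
    components: Tuple[SoundComponent, ...] = field(default_factory=_default_components)

    def corpus_spec(self, seed: int) -> SyntheticCorpusSpec:
        return SyntheticCorpusSpec(
            n_recorders=self.n_recorders,
            n_days=self.n_days,
            recordings_per_hour=self.recordings_per_hour,
            duration_s=self.duration_s,
            sample_rate=self.sample_rate,
            components=self.components,
            noise_floor=self.noise_floor,
            seed=seed,
        )


@dataclass(frozen=True)
class IngestStage:
    rain_threshold_db: Optional[float] = None  # None disables the rain screen


@dataclass(frozen=True)
class ProjectStage:
    methods: Tuple[str, ...] = ("pca", "umap")
    n_components: int = 60
    normalize: bool = True

    def __post_init__(self):
        object.__setattr__(self, "methods", tuple(self.methods))
        for m in self.methods:
            if m not in project_mod.PROJECTION_METHODS:
                raise ValueError(f"unknown projection method {m!r}")


@dataclass(frozen=True)
class ClusterStage:
    space: str = "umap"  # full_embedding or a projection method
    k: int = 3
    sweep: Optional[Tuple[int, ...]] = None

    def __post_init__(self):
        if self.sweep is not None:
            object.__setattr__(self, "sweep", tuple(self.sweep))
        if self.k < 2:
            raise ValueError("cluster.k must be >= 2")


@dataclass(frozen=True)
class ClassifyStage:
    enabled: bool = True
    split_fraction: float = 0.8
    max_depth: int = 16

    def __post_init__(self):
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError(f"classify.split_fraction {self.split_fraction} not in (0, 1)")


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    synth: SynthStage = field(default_factory=SynthStage)
    ingest: IngestStage = field(default_factory=IngestStage)
    cae: cae_mod.AutoencoderConfig = field(default_factory=lambda: cae_mod.AutoencoderConfig(epochs=2))
    project: ProjectStage = field(default_factory=ProjectStage)
    cluster: ClusterStage = field(default_factory=ClusterStage)
    classify: ClassifyStage = field(default_factory=ClassifyStage)

    def stage_seed(self, stage: str) -> int:
        return self.seed + STAGE_ORDER.index(stage)

    def to_dict(self) -> dict:
        d = asdict(self)
        for comp in d["synth"]["components"]:
            comp["active_hours"] = sorted(comp["active_hours"])
        return d


def _build_section(cls, data: dict, path: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in config section {path!r}")
    return cls(**data)


def config_from_dict(data: dict) -> PipelineConfig:
    """Build and validate a PipelineConfig; unknown keys are rejected."""
    data = dict(data)
    sections = {}
    if "synth" in data:
        synth = dict(data.pop("synth"))
        comps = synth.pop("components", None)
        if comps is not None:
            built = []
            for i, c in enumerate(comps):
                c = dict(c)
                if "active_hours" in c:
                    c["active_hours"] = frozenset(int(h) for h in c["active_hours"])
                comp_known = {f.name for f in dataclasses.fields(SoundComponent)}
                unknown = set(c) - comp_known
                if unknown:
                    raise ValueError(f"unknown key(s) {sorted(unknown)} in synth.components[{i}]")
                built.append(SoundComponent(**c))
            synth["components"] = tuple(built)
        sections["synth"] = _build_section(SynthStage, synth, "synth")
    for name, cls in [
        ("ingest", IngestStage),
        ("cae", cae_mod.AutoencoderConfig),
        ("project", ProjectStage),
        ("cluster", ClusterStage),
        ("classify", ClassifyStage),
    ]:
        if name in data:
            section = dict(data.pop(name))
            for key in ("channel_progression", "strides", "paddings", "methods", "sweep"):
                if key in section and section[key] is not None:
                    section[key] = tuple(section[key])
            sections[name] = _build_section(cls, section, name)
    seed = data.pop("seed", 0)
    if data:
        raise ValueError(f"unknown top-level config key(s) {sorted(data)}")
    return PipelineConfig(seed=int(seed), **sections)


def load_config(path) -> PipelineConfig:
    """Load a YAML pipeline config, validating every section up front."""
    import yaml

    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    return config_from_dict(raw)


# ---------------------------------------------------------------------------
# checksums and caching

def artifact_checksum(path) -> str:
    """Content checksum; HDF5/npz are hashed by dataset contents so the
    checksum reflects the data, not container bookkeeping bytes."""
    path = Path(path)
    h = hashlib.sha256()
    if path.suffix == ".h5":
        import h5py

        with h5py.File(path, "r") as f:
            def visit(name, obj):
                if isinstance(obj, h5py.Dataset):
                    h.update(name.encode())
                    data = obj[()]
                    arr = np.asarray(data)
                    if arr.dtype == object or arr.dtype.kind in "SU":
                        for item in arr.ravel():
                            h.update(item if isinstance(item, bytes) else str(item).encode())
                            h.update(b"\x00")
                    else:
                        h.update(np.ascontiguousarray(arr).tobytes())
            f.visititems(visit)
    elif path.suffix == ".npz":
        with np.load(path) as archive:
            for key in sorted(archive.files):
                h.update(key.encode())
                h.update(np.ascontiguousarray(archive[key]).tobytes())
    else:
        h.update(path.read_bytes())
    return h.hexdigest()


def _stage_hash(config_piece: dict, input_checksums: Sequence[str]) -> str:
    payload = json.dumps({"config": config_piece, "inputs": list(input_checksums)}, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


class _StageGuard:
    """Skip-or-run decision for one stage based on a persisted hash."""

    def __init__(self, run_dir: Path, name: str, stage_hash: str, outputs: Sequence[Path]):
        self.hash_file = run_dir / f".{name}.hash"
        self.stage_hash = stage_hash
        self.outputs = [Path(p) for p in outputs]

    @property
    def cached(self) -> bool:
        return (
            self.hash_file.exists()
            and self.hash_file.read_text().strip() == self.stage_hash
            and all(p.exists() for p in self.outputs)
        )

    def mark_done(self) -> None:
        self.hash_file.write_text(self.stage_hash)


@dataclass
class RunResult:
    run_dir: Path
    summary: dict
    stage_status: Dict[str, str]  # "computed" | "cached" | "skipped"


# ---------------------------------------------------------------------------

def _summarize(entries: Dict[str, dict]) -> dict:
    return {stage: entries[stage] for stage in STAGE_ORDER if stage in entries}


def run_pipeline(config: PipelineConfig, out_dir) -> RunResult:
    """Execute all stages in order; returns the run summary and per-stage
    status.  Any stage failure propagates with the stage named; artifacts
    of completed stages are preserved."""
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    status: Dict[str, str] = {}
    summary: Dict[str, dict] = {}
    t_run = time.time()

    def _log_stage(name: str, state: str, t0: float, **counts):
        logger.info("stage=%s status=%s wall_s=%.1f %s", name, state, time.time() - t0,
                    " ".join(f"{k}={v}" for k, v in counts.items()))

    try:
        # ---- synth -------------------------------------------------------
        t0 = time.time()
        if config.synth.input_dir is not None:
            corpus_dir = Path(config.synth.input_dir)
            manifest_path = corpus_dir / "manifest.csv"
            if not manifest_path.exists():
                raise FileNotFoundError(f"no manifest.csv in input corpus {corpus_dir}")
            status["synth"] = "skipped"
        else:
            corpus_dir = run_dir / "corpus"
            manifest_path = corpus_dir / "manifest.csv"
            spec = config.synth.corpus_spec(config.stage_seed("synth"))
            guard = _StageGuard(run_dir, "synth", _stage_hash(config.to_dict()["synth"] | {"seed": spec.seed}, []),
                                [manifest_path])
            if guard.cached:
                status["synth"] = "cached"
            else:
                generate_corpus(spec, corpus_dir)
                guard.mark_done()
                status["synth"] = "computed"
        manifest_checksum = artifact_checksum(manifest_path)
        import pandas as pd

        manifest = pd.read_csv(manifest_path)
        summary["synth"] = {
            "outputs": {"manifest.csv": manifest_checksum},
            "counts": {"recordings": int(len(manifest))},
        }
        _log_stage("synth", status["synth"], t0, recordings=len(manifest))

        # ---- spectro (ingest + STFT) ------------------------------------
        t0 = time.time()
        spectra_path = run_dir / "spectra.h5"
        index_path = run_dir / "segment_index.csv"
        guard = _StageGuard(
            run_dir, "spectro",
            _stage_hash({"ingest": config.to_dict()["ingest"]}, [manifest_checksum]),
            [spectra_path, index_path],
        )
        if guard.cached:
            status["spectro"] = "cached"
        else:
            segments, kept_flags, specs = [], [], []
            for _, row in manifest.iterrows():
                wav_path = Path(row["path"])
                if not wav_path.is_absolute():
                    wav_path = corpus_dir / wav_path
                rec, wave = ingest_mod.load_recording(wav_path, manifest_row=row)
                keep = True
                if config.ingest.rain_threshold_db is not None:
                    keep, _score = ingest_mod.rain_filter(
                        wave, rec.sample_rate, config.ingest.rain_threshold_db
                    )
                for seg in ingest_mod.segment_recording(rec, wave):
                    segments.append(seg)
                    kept_flags.append(keep)
                    if keep:
                        specs.append(spectro_mod.stft_spectrogram(seg))
            ingest_mod.build_segment_index(segments, kept_flags).to_csv(index_path, index=False)
            spectro_mod.save_spectrograms(spectra_path, specs)
            guard.mark_done()
            status["spectro"] = "computed"
        spectra_checksum = artifact_checksum(spectra_path)
        index_checksum = artifact_checksum(index_path)
        spectra, segment_ids = spectro_mod.load_spectrograms(spectra_path)
        summary["spectro"] = {
            "outputs": {"spectra.h5": spectra_checksum, "segment_index.csv": index_checksum},
            "counts": {"spectrograms": int(len(spectra))},
        }
        _log_stage("spectro", status["spectro"], t0, spectrograms=len(spectra))

        # ---- train -------------------------------------------------------
        t0 = time.time()
        model_path = run_dir / "model.npz"
        cae_cfg = dataclasses.replace(config.cae, seed=config.stage_seed("train"))
        guard = _StageGuard(run_dir, "train", _stage_hash(asdict(cae_cfg), [spectra_checksum]), [model_path])
        if guard.cached:
            status["train"] = "cached"
            model = cae_mod.load_checkpoint(model_path)
        else:
            model = cae_mod.build_autoencoder(cae_cfg)
            groups = [sid.rsplit("#", 1)[0] for sid in segment_ids]
            log = cae_mod.train(model, spectra, cae_cfg, groups=groups)
            cae_mod.save_checkpoint(model_path, model)
            pd.DataFrame(log).to_csv(run_dir / "training_log.csv", index=False)
            guard.mark_done()
            status["train"] = "computed"
        model_checksum = artifact_checksum(model_path)
        summary["train"] = {"outputs": {"model.npz": model_checksum}, "counts": {"epochs": cae_cfg.epochs}}
        _log_stage("train", status["train"], t0, epochs=cae_cfg.epochs)

        # ---- embed -------------------------------------------------------
        t0 = time.time()
        emb_path = run_dir / "embeddings.h5"
        guard = _StageGuard(run_dir, "embed", _stage_hash({}, [model_checksum, spectra_checksum]), [emb_path])
        if guard.cached:
            status["embed"] = "cached"
        else:
            import h5py

            chunks = [model.encode(spectra[i : i + 16]) for i in range(0, len(spectra), 16)]
            embeddings = np.concatenate(chunks, axis=0)
            with h5py.File(emb_path, "w") as f:
                f.create_dataset("embeddings", data=embeddings.astype(np.float32))
                f.create_dataset("segment_ids", data=np.array(segment_ids, dtype=h5py.string_dtype()))
            guard.mark_done()
            status["embed"] = "computed"
        import h5py

        with h5py.File(emb_path, "r") as f:
            embeddings = f["embeddings"][:].astype(np.float64)
        emb_checksum = artifact_checksum(emb_path)
        summary["embed"] = {"outputs": {"embeddings.h5": emb_checksum}, "counts": {"embeddings": int(len(embeddings))}}
        _log_stage("embed", status["embed"], t0, embeddings=len(embeddings))

        # ---- project -----------------------------------------------------
        t0 = time.time()
        import joblib

        proj_seed = config.stage_seed("project")
        proj_path = run_dir / "projections.h5"
        proj_models_path = run_dir / ".projection_models.joblib"
        guard = _StageGuard(
            run_dir, "project",
            _stage_hash(config.to_dict()["project"] | {"seed": proj_seed}, [emb_checksum]),
            [proj_path, proj_models_path],
        )
        if guard.cached:
            status["project"] = "cached"
            proj_models = joblib.load(proj_models_path)
            projections = {}
            with h5py.File(proj_path, "r") as f:
                for method in config.project.methods:
                    projections[method] = f[f"projections/{method}_{config.project.n_components}"][:]
        else:
            projections, proj_models = {}, {}
            for method in config.project.methods:
                pm, coords = project_mod.fit_project(
                    embeddings, method=method, n_components=config.project.n_components,
                    seed=proj_seed, normalize=config.project.normalize,
                )
                projections[method] = coords
                proj_models[method] = pm
            with h5py.File(proj_path, "w") as f:
                for method, coords in projections.items():
                    f.create_dataset(f"projections/{method}_{config.project.n_components}", data=coords)
            joblib.dump(proj_models, proj_models_path)
            guard.mark_done()
            status["project"] = "computed"
        proj_checksum = artifact_checksum(proj_path)
        summary["project"] = {
            "outputs": {"projections.h5": proj_checksum},
            "counts": {"methods": len(projections), "n_components": config.project.n_components},
        }
        _log_stage("project", status["project"], t0, methods=len(projections))

        # ---- cluster -----------------------------------------------------
        t0 = time.time()
        space = config.cluster.space
        if space == "full_embedding":
            feats = project_mod.normalize_features(embeddings) if config.project.normalize else embeddings
        elif space in projections:
            feats = projections[space]
        else:
            raise ValueError(f"cluster.space {space!r} not among computed projections {list(projections)}")
        cluster_seed = config.stage_seed("cluster")
        assign_path = run_dir / "assignments.csv"
        validity_path = run_dir / "validity.json"
        cmodel_path = run_dir / ".cluster_model.joblib"
        sweep_path = run_dir / "sweep.csv"
        cluster_outputs = [assign_path, validity_path, cmodel_path] + ([sweep_path] if config.cluster.sweep else [])
        guard = _StageGuard(
            run_dir, "cluster",
            _stage_hash(config.to_dict()["cluster"] | {"seed": cluster_seed}, [emb_checksum, proj_checksum]),
            cluster_outputs,
        )
        if guard.cached:
            status["cluster"] = "cached"
            cmodel = joblib.load(cmodel_path)
        else:
            cmodel = cluster_mod.kmeans(feats, config.cluster.k, seed=cluster_seed, feature_space=space)
            report = cluster_mod.validity_metrics(feats, cmodel)
            pd.DataFrame(
                {"segment_id": segment_ids, "k": config.cluster.k, "cluster": cmodel.assignments}
            ).to_csv(assign_path, index=False)
            if config.cluster.sweep:
                sweep_table, _best = cluster_mod.k_sweep(
                    feats, config.cluster.sweep, seed=cluster_seed, feature_space=space
                )
                sweep_table.to_csv(sweep_path, index=False)
            validity_path.write_text(json.dumps({
                "k": config.cluster.k,
                "space": space,
                "energy": cmodel.energy,
                "silhouette": report.silhouette_avg,
                "calinski_harabasz": report.calinski_harabasz,
                "davies_bouldin": report.davies_bouldin,
            }, indent=2, sort_keys=True))
            joblib.dump(cmodel, cmodel_path)
            guard.mark_done()
            status["cluster"] = "computed"
        outputs = {"assignments.csv": artifact_checksum(assign_path),
                   "validity.json": artifact_checksum(validity_path)}
        if config.cluster.sweep:
            outputs["sweep.csv"] = artifact_checksum(sweep_path)
        cluster_checksum = outputs["assignments.csv"]
        summary["cluster"] = {"outputs": outputs, "counts": {"k": config.cluster.k}}
        _log_stage("cluster", status["cluster"], t0, k=config.cluster.k)

        # ---- interpret ---------------------------------------------------
        t0 = time.time()
        proto_path = run_dir / "prototypes.h5"
        diel_path = run_dir / "diel.csv"
        guard = _StageGuard(
            run_dir, "interpret",
            _stage_hash({}, [model_checksum, emb_checksum, cluster_checksum]),
            [proto_path, diel_path],
        )
        if guard.cached:
            status["interpret"] = "cached"
            with h5py.File(proto_path, "r") as f:
                n_protos = len(f["prototypes"])
        else:
            protos = []
            inv_proj = proj_models.get(space) if space in ("pca", "umap") else None
            for j in range(cmodel.k):
                protos.append(
                    interpret_mod.prototype_spectrogram(
                        cmodel, model, j, projection=inv_proj, member_embeddings=embeddings, pathway="auto"
                    )
                )
            with h5py.File(proto_path, "w") as f:
                f.create_dataset(
                    "prototypes", data=np.stack([p.values for p in protos]).astype(np.float32)
                )
            index = pd.read_csv(index_path)
            index = index.set_index("segment_id").loc[segment_ids]
            hours = pd.to_datetime(index["timestamp_iso"]).dt.hour.to_numpy()
            hists = interpret_mod.diel_histograms(cmodel.assignments, hours, cmodel.k)
            pd.DataFrame(
                [
                    {"cluster": h.cluster_index, "hour": hour, "count": int(h.counts[hour])}
                    for h in hists
                    for hour in range(24)
                ]
            ).to_csv(diel_path, index=False)
            n_protos = len(protos)
            status["interpret"] = "computed"
            guard.mark_done()
        summary["interpret"] = {
            "outputs": {
                "prototypes.h5": artifact_checksum(proto_path),
                "diel.csv": artifact_checksum(diel_path),
            },
            "counts": {"prototypes": int(n_protos)},
        }
        _log_stage("interpret", status["interpret"], t0, prototypes=n_protos)

        # ---- classify ----------------------------------------------------
        if config.classify.enabled:
            t0 = time.time()
            index = pd.read_csv(index_path).set_index("segment_id").loc[segment_ids]
            labels = index["path"].map(manifest.set_index("path")["cover_label"]).to_numpy()
            if len(set(labels.tolist())) == 2:
                cls_path = run_dir / "classification.csv"
                guard = _StageGuard(
                    run_dir, "classify",
                    _stage_hash(config.to_dict()["classify"] | {"seed": config.stage_seed("classify")},
                                [emb_checksum, proj_checksum]),
                    [cls_path],
                )
                if guard.cached:
                    status["classify"] = "cached"
                    n_spaces = len(pd.read_csv(cls_path))
                else:
                    spaces = {"full_embedding": embeddings, **projections}
                    table = supervised_mod.compare_feature_spaces(
                        spaces, labels,
                        split_fraction=config.classify.split_fraction,
                        max_depth=config.classify.max_depth,
                        seed=config.stage_seed("classify"),
                    )
                    table.to_csv(cls_path, index=False)
                    n_spaces = len(spaces)
                    status["classify"] = "computed"
                    guard.mark_done()
                summary["classify"] = {
                    "outputs": {"classification.csv": artifact_checksum(cls_path)},
                    "counts": {"spaces": int(n_spaces)},
                }
                _log_stage("classify", status["classify"], t0, spaces=n_spaces)
            else:
                status["classify"] = "skipped"
                logger.info("stage=classify status=skipped reason=single-class-labels")
        else:
            status["classify"] = "skipped"

    except Exception as exc:
        failed = next((s for s in STAGE_ORDER if s not in status), "unknown")
        raise RuntimeError(f"pipeline failed at stage {failed!r}: {exc}") from exc

    ordered = _summarize(summary)
    (run_dir / "summary.json").write_text(json.dumps(ordered, indent=2, sort_keys=True))
    logger.info("pipeline complete in %.1f s", time.time() - t_run)
    return RunResult(run_dir=run_dir, summary=ordered, stage_status=status)
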
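"""Plain-text serialisation and end-to-end orchestration.

Cohorts live on disk as one dense CSV matrix per sample (first row = drift
axis, first column = retention axis) plus a TSV manifest (sample_id, file,
label) and, for simulations, a TSV truth table of planted peak coordinates.
Everything is reviewable text; cohort sizes at desk scale stay manageable.

`run_end_to_end` chains simulate (or load) -> preprocess -> flatten ->
cross-validate -> report, persisting each stage's output together with a run
record (config, seed, library versions) so every artifact is reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ParseError
from .evaluate import DiagnosticsReport, build_report
from .pipeline import CVConfig, CVResult, FeatureTable, flatten, run_cv
from .preprocess import PreprocessConfig, preprocess_cohort
from .simulate import PeakSpec, RipSpec, SimulationConfig, simulate_cohort
from .spectra import Cohort, Spectrum

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_feature_table",
    "read_feature_table",
    "write_cv_result",
    "write_report",
    "RunConfig",
    "run_end_to_end",
]

logger = logging.getLogger(__name__)

_CORNER = "retention\\drift"


# ------------------------------------------------------------ cohort on disk


def write_spectrum_csv(spectrum: Spectrum, path: Path) -> None:
    df = pd.DataFrame(
        spectrum.intensities,
        index=spectrum.retention_axis,
        columns=spectrum.drift_axis,
    )
    df.index.name = _CORNER
    df.to_csv(path, float_format="%.10g")


def read_spectrum_csv(path: Path, sample_id: str = "") -> Spectrum:
    if not Path(path).exists():
        raise ParseError(f"spectrum file not found: {path}")
    df = pd.read_csv(path, index_col=0)
    return Spectrum(
        df.to_numpy(dtype=float),
        df.index.to_numpy(dtype=float),
        df.columns.to_numpy(dtype=float),
        sample_id=sample_id,
    )


def write_cohort(cohort: Cohort, out_dir: Path) -> Path:
    """Write per-sample CSVs, manifest.tsv and truth.tsv; returns the
    manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for spectrum, label in zip(cohort.spectra, cohort.labels):
        fname = f"{spectrum.sample_id}.csv"
        write_spectrum_csv(spectrum, out_dir / fname)
        rows.append({"sample_id": spectrum.sample_id, "file": fname, "label": int(label)})
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    pd.DataFrame(
        cohort.truth, columns=["retention_center", "drift_center", "class_effect"]
    ).to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return manifest


def read_cohort(manifest_path: Path) -> Cohort:
    """Load a cohort from its manifest; axes validated identical, labels
    binary.  Errors name the offending sample."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise ParseError(f"manifest not found: {manifest_path}")
    df = pd.read_csv(manifest_path, sep="\t")
    for col in ("sample_id", "file", "label"):
        if col not in df.columns:
            raise ParseError(f"manifest missing column {col!r}")
    labels = df["label"].to_numpy()
    bad = set(np.unique(labels)) - {0, 1}
    if bad:
        raise ParseError(f"non-binary labels in manifest: {sorted(bad)}")
    spectra = []
    for _, row in df.iterrows():
        path = manifest_path.parent / row["file"]
        if not path.exists():
            raise ParseError(
                f"sample {row['sample_id']!r}: spectrum file not found: {path}"
            )
        spectra.append(read_spectrum_csv(path, sample_id=str(row["sample_id"])))
    truth_path = manifest_path.parent / "truth.tsv"
    truth: list[tuple[float, float, float]] = []
    if truth_path.exists():
        tdf = pd.read_csv(truth_path, sep="\t")
        truth = [tuple(r) for r in tdf.to_numpy(dtype=float)]
    cohort = Cohort(spectra, labels.astype(int), truth)
    cohort.validate_axes()
    return cohort


# ---------------------------------------------------- feature table / results


def write_feature_table(table: FeatureTable, path: Path) -> None:
    df = pd.DataFrame(table.values, index=table.sample_ids, columns=table.feature_names())
    df.index.name = "sample_id"
    df.insert(0, "label", table.labels)
    df.to_csv(path, sep="\t", float_format="%.10g")
    axes_path = Path(path).with_suffix(".axes.json")
    axes_path.write_text(
        json.dumps(
            {
                "retention_axis": table.retention_axis.tolist(),
                "drift_axis": table.drift_axis.tolist(),
            }
        )
    )


def read_feature_table(path: Path) -> FeatureTable:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"feature table not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    axes = json.loads(path.with_suffix(".axes.json").read_text())
    labels = df.pop("label").to_numpy(dtype=int)
    return FeatureTable(
        df.to_numpy(dtype=float),
        np.asarray(axes["retention_axis"], dtype=float),
        np.asarray(axes["drift_axis"], dtype=float),
        [str(s) for s in df.index],
        labels,
    )


def write_cv_result(result: CVResult, table: FeatureTable, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "sample_id": table.sample_ids,
            "label": table.labels,
            "fold": result.fold_assignment,
            "oof_probability": result.oof_probability,
        }
    ).to_csv(out_dir / "oof_probabilities.tsv", sep="\t", index=False)
    rows = []
    for fold, (idx, p) in enumerate(
        zip(result.selected_features, result.selected_pvalues)
    ):
        for rank, (j, pj) in enumerate(zip(idx, p)):
            rows.append({"fold": fold, "rank": rank, "feature": int(j), "p_value": pj})
    pd.DataFrame(rows).to_csv(out_dir / "selected_features.tsv", sep="\t", index=False)


def write_report(report: DiagnosticsReport, path: Path) -> None:
    path = Path(path)
    path.write_text(report.to_json() + "\n")
    tsv = path.with_suffix(".tsv")
    pd.DataFrame([report.to_dict()]).to_csv(tsv, sep="\t", index=False)


# ------------------------------------------------------------ run end-to-end


@dataclass
class RunConfig:
    """Composite configuration for one reproducible run.

    One global seed fans out to per-stage seeds (simulation, CV) through
    independent child streams of ``numpy.random.SeedSequence(seed)``, in
    stage order.
    """

    simulation: SimulationConfig | None = None
    cohort_manifest: str | None = None
    preprocess: PreprocessConfig = field(
        default_factory=lambda: PreprocessConfig(
            crop_window=(0.0, 60.0, 0.0, 60.0),
            rip_line_retention=(57.0, 60.0),
        )
    )
    cv: CVConfig = field(default_factory=CVConfig)
    ci_method: str = "delong"
    seed: int = 0

    def stage_seeds(self) -> tuple[int, int]:
        """(simulation_seed, cv_seed), each below 2**31."""
        children = np.random.SeedSequence(self.seed).spawn(2)
        return tuple(int(c.generate_state(1)[0] % (2**31)) for c in children)

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        sim = None
        if "simulation" in raw and raw["simulation"] is not None:
            s = dict(raw["simulation"])
            if "peaks" in s:
                s["peaks"] = tuple(PeakSpec(**p) for p in s["peaks"])
            if "rip" in s:
                s["rip"] = RipSpec(**s["rip"])
            sim = SimulationConfig(**s)
        pp = raw.get("preprocess")
        preprocess = (
            PreprocessConfig(
                crop_window=tuple(pp["crop_window"]),
                rip_line_retention=tuple(pp["rip_line_retention"]),
                rip_mode=pp.get("rip_mode", "per_sample"),
                threshold=pp.get("threshold", "auto"),
            )
            if pp
            else cls().preprocess
        )
        cv = CVConfig(**raw["cv"]) if raw.get("cv") else CVConfig()
        return cls(
            simulation=sim,
            cohort_manifest=raw.get("cohort_manifest"),
            preprocess=preprocess,
            cv=cv,
            ci_method=raw.get("ci_method", "delong"),
            seed=int(raw.get("seed", 0)),
        )


def _run_record(config: RunConfig) -> dict:
    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    return {
        "vocims_version": __version__,
        "numpy_version": np.__version__,
        "config": encode(config),
    }


def run_end_to_end(config: RunConfig, out_dir: Path | None = None) -> DiagnosticsReport:
    """simulate (or load) -> preprocess -> flatten -> cross-validate -> report.

    With ``out_dir`` set, every stage output plus the run record is persisted;
    identical config (incl. seed) produces byte-identical report files.
    """
    sim_seed, cv_seed = config.stage_seeds()

    if config.cohort_manifest is not None:
        logger.info("stage load: %s", config.cohort_manifest)
        cohort = read_cohort(config.cohort_manifest)
    elif config.simulation is not None:
        logger.info("stage simulate")
        sim = dataclasses.replace(config.simulation, seed=sim_seed)
        cohort = simulate_cohort(sim)
    else:
        raise ParseError("RunConfig needs either a simulation or a cohort_manifest")

    logger.info("stage preprocess")
    processed = preprocess_cohort(cohort, config.preprocess)
    logger.info("stage flatten")
    table = flatten(processed)
    logger.info("stage cross-validate (%s)", config.cv.classifier)
    cv = dataclasses.replace(config.cv, seed=cv_seed)
    result = run_cv(table, cv)
    logger.info("stage report")
    report = build_report(result, table.labels, ci_method=config.ci_method)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        if config.cohort_manifest is None:
            write_cohort(cohort, out_dir / "cohort")
        write_feature_table(table, out_dir / "features.tsv")
        write_cv_result(result, table, out_dir / "cv")
        write_report(report, out_dir / "report.json")
        (out_dir / "run_record.json").write_text(
            json.dumps(_run_record(config), indent=2, sort_keys=True) + "\n"
        )
    return report
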
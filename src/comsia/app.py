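"""End-to-end runner, configuration, synthetic fixture generator, and CLI.

``run_comsia`` executes the whole pipeline — read (and optionally align) →
shared grid → five similarity fields → filter/scale/center → LOOCV component
selection → final PLS fit → external prediction → coefficient contour meshes —
and writes the standard artifact files (metrics TSV, predictions CSV, CV
curve, meshes, run log, warnings).

``generate_fixture`` builds small synthetic aligned molecule sets with
activities that are by construction a linear function of one field's grid
columns plus Gaussian noise, so every downstream stage (and parameter
recovery) is testable offline.
"""

from __future__ import annotations

import json

import platform
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .alignment import align_set
from .chemio import (
    Molecule,
    MoleculeSet,
    annotate_set,
    read_sdf,
    read_smiles_table,
    write_sdf,
)
from .contour import coefficient_map, export_contours, extract_isosurfaces, percentile_thresholds
from .fields import FieldConfig, compute_all_fields
from .grid import build_grid
from .pls import evaluate_test, fit_final, loocv, predict, select_components
from .preprocess import build_feature_matrix

__all__ = [
    "RunConfig",
    "FixtureSpec",
    "RunResult",
    "run_comsia",
    "generate_fixture",
    "summarize_activities",
    "main",
]


@dataclass
class RunConfig:
    """All knobs of an end-to-end run, with the benchmark-standard defaults."""

    train_path: str = ""
    test_path: str | None = None
    predict_path: str | None = None
    activity_tag: str = "activity"
    grid_spacing: float = 1.0
    grid_padding: float = 4.0
    alpha: float = 0.3
    fields_enabled: str = "SEH"
    pseudo_distance: float = 1.9
    clash_factor: float = 0.7
    snap: bool = True
    max_components: int | None = None
    filter_threshold: float | None = None
    per_column_scaling: bool = False
    top_fraction: float = 0.05
    contour_fields: str = "all"
    seed: int = 42
    align: bool = False
    template: str | None = None
    output_dir: str = "results"

    def field_config(self) -> FieldConfig:
        return FieldConfig(
            alpha=self.alpha,
            fields_enabled=self.fields_enabled,
            pseudo_distance=self.pseudo_distance,
            clash_factor=self.clash_factor,
            snap=self.snap,
        )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class RunResult:
    config: RunConfig
    cv_curve: object
    model: object
    feature_matrix: object
    predictions: dict[str, float]
    metrics: dict[str, float]
    output_dir: Path
    warnings: list[str] = dc_field(default_factory=list)


def summarize_activities(mset: MoleculeSet | list[float]) -> tuple[float, float | None]:
    """Arithmetic mean and sample (n-1) standard deviation of activities."""
    if isinstance(mset, MoleculeSet):
        values = [m.activity for m in mset]
        if any(v is None for v in values):
            raise ValueError("activity missing for some molecules")
    else:
        values = list(mset)
    if not values:
        raise ValueError("no activities to summarize")
    arr = np.array(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if len(arr) >= 2 else None
    return mean, sd


def _load_set(path: str, activity_tag: str, role: str, cfg: RunConfig):
    p = Path(path)
    if p.suffix.lower() == ".csv":
        mset = read_smiles_table(p)
    else:
        mset = read_sdf(p, activity_tag=activity_tag)
    mset.role = role
    return mset


def run_comsia(cfg: RunConfig) -> RunResult:
    """Execute the full pipeline described in the module docstring."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    notes: list[str] = []

    stage = "input"
    try:
        train = _load_set(cfg.train_path, cfg.activity_tag, "train", cfg)
        others = []
        if cfg.test_path:
            others.append(_load_set(cfg.test_path, cfg.activity_tag, "test", cfg))
        if cfg.predict_path:
            others.append(_load_set(cfg.predict_path, cfg.activity_tag, "predict", cfg))

        stage = "alignment"
        if cfg.align or any(m.needs_embedding for s in [train] + others for m in s):
            merged = MoleculeSet(
                [m for s in [train] + others for m in s], role="train"
            )
            result = align_set(merged, seed=cfg.seed, template=cfg.template)
            notes.extend(result.warnings)
            by_name = {m.name: m for m in result.aligned}
            train = MoleculeSet([by_name[n] for n in train.names], role="train")
            others = [
                MoleculeSet([by_name[n] for n in s.names], role=s.role) for s in others
            ]
            rmsd_path = out / "core_rmsd.tsv"
            with open(rmsd_path, "w") as fh:
                fh.write("molecule\tcore_rmsd\n")
                for name, rmsd in zip(result.aligned.names, result.core_rmsd):
                    fh.write(f"{name}\t{rmsd:.4f}\n")

        stage = "annotation"
        train = annotate_set(train)
        others = [annotate_set(s) for s in others]

        stage = "grid"
        grid = build_grid([train] + others, spacing=cfg.grid_spacing,
                          padding=cfg.grid_padding, snap=cfg.snap)

        stage = "fields"
        fcfg = cfg.field_config()
        train_tensor = compute_all_fields(train, grid, fcfg)
        other_tensors = [compute_all_fields(s, grid, fcfg) for s in others]
        notes.extend(train_tensor.warnings)
        for t in other_tensors:
            notes.extend(t.warnings)

        stage = "preprocess"
        activities = list(train.activities) + [
            a for s in others for a in s.activities
        ]
        fm = build_feature_matrix(
            train_tensor,
            *other_tensors,
            activities=activities,
            filter_threshold=cfg.filter_threshold,
            per_column_scaling=cfg.per_column_scaling,
        )

        stage = "pls"
        curve = loocv(fm, max_components=cfg.max_components)
        k_opt = select_components(curve)
        model = fit_final(fm, k_opt)
        metrics = {
            "q2": curve.q2[k_opt - 1],
            "s_press": curve.s_press[k_opt - 1],
            "r2_train": model.metrics["r2_train"],
            "s_train": model.metrics["s_train"],
            "n_components": k_opt,
        }
        metrics.update(evaluate_test(model, fm, role="test"))

        predictions: dict[str, float] = {}
        for role in ("train", "test", "predict"):
            rows = fm.rows(role)
            if rows.shape[0] == 0:
                continue
            names = [n for n, r in zip(fm.row_names, fm.roles) if r == role]
            for name, val in zip(names, predict(model, rows)):
                predictions[name] = float(val)

        stage = "contours"
        wanted = (
            model.field_contributions.keys()
            if cfg.contour_fields == "all"
            else list(cfg.contour_fields)
        )
        for fname in wanted:
            cmap = coefficient_map(model, grid, fname)
            try:
                thresholds = percentile_thresholds(cmap, cfg.top_fraction)
            except ValueError as exc:
                notes.append(str(exc))
                continue
            cset = extract_isosurfaces(cmap, thresholds)
            export_contours(cset, out / "contours", formats=("obj", "vtk"))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    _write_artifacts(out, cfg, curve, model, metrics, predictions, fm, notes)
    return RunResult(
        config=cfg,
        cv_curve=curve,
        model=model,
        feature_matrix=fm,
        predictions=predictions,
        metrics=metrics,
        output_dir=out,
        warnings=notes,
    )


def _write_artifacts(out, cfg, curve, model, metrics, predictions, fm, notes):
    with open(out / "metrics.tsv", "w") as fh:
        fh.write("metric\tvalue\n")
        for key in ("q2", "s_press", "r2_train", "s_train", "n_components",
                    "r2_pred", "s_test"):
            if key in metrics:
                val = metrics[key]
                fh.write(f"{key}\t{val:.6f}\n" if isinstance(val, float) else f"{key}\t{val}\n")
        for fname, frac in sorted(model.field_contributions.items()):
            fh.write(f"contribution_{fname}\t{frac:.6f}\n")

    with open(out / "cv_curve.csv", "w") as fh:
        fh.write("components,PRESS,q2,S_PRESS\n")
        for k, press, q2, s_press in curve.as_rows():
            fh.write(f"{k},{press:.6f},{q2:.6f},{s_press:.6f}\n")

    with open(out / "predictions.csv", "w") as fh:
        fh.write("name,role,activity,predicted,residual\n")
        for name, role, act in zip(fm.row_names, fm.roles, fm.activities):
            pred = predictions.get(name)
            if pred is None:
                continue
            if act is None:
                fh.write(f"{name},{role},,{pred:.4f},\n")
            else:
                fh.write(f"{name},{role},{act},{pred:.4f},{act - pred:.4f}\n")

    log = {
        "config": asdict(cfg),
        "versions": {
            "python": platform.python_version(),
            "comsia": __version__,
        },
        "seed": cfg.seed,
        "metrics": {k: (float(v) if isinstance(v, float) else v)
                    for k, v in metrics.items()},
    }
    (out / "run_log.yaml").write_text(yaml.safe_dump(log, sort_keys=True))
    (out / "warnings.json").write_text(json.dumps(notes, indent=2))


# ---------------------------------------------------------------------------
# Synthetic fixture generation

# Substituents crossed over size and polarity so the five fields decorrelate
# as far as a one-site series allows.  Written attachment-atom-last so that
# fragment + scaffold concatenates into valid SMILES.
DEFAULT_SUBSTITUENTS: tuple[str, ...] = (
    "C", "CC", "CCC", "CC(C)", "CCCC", "O", "CO", "OC", "OCC", "COC",
    "N", "CN", "NC", "NCC", "F", "Cl", "Br", "I", "FC", "ClC",
    "C(F)(F)(F)", "N#C", "N#CC", "S", "CS", "SC", "C=C", "CC=C", "OC(=O)",
    "CC(=O)", "O=C", "OCCC", "NCCC", "BrC", "FCC",
)


@dataclass
class FixtureSpec:
    """Recipe for a synthetic aligned molecule set with planted activities."""

    n_train: int = 20
    n_test: int = 5
    scaffold: str = "C1CCCCC1"
    substituent_set: tuple[str, ...] = DEFAULT_SUBSTITUENTS
    noise_sd: float = 0.1
    true_field: str = "E"
    seed: int = 0
    grid_spacing: float = 1.0
    grid_padding: float = 4.0
    alpha: float = 0.3
    fields_enabled: str = "SEHAD"
    signal_sd: float = 1.2

    def __post_init__(self) -> None:
        if self.n_train < 5:
            raise ValueError("n_train must be >= 5")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class FixtureTruth:
    true_field: str
    signal_sd: float
    noise_sd: float
    seed: int
    top_loading_grid_indices: list[int]
    top_loadings: list[float]
    activities: dict[str, float]


def generate_fixture(
    spec: FixtureSpec,
) -> tuple[MoleculeSet, MoleculeSet, FixtureTruth]:
    """Build aligned train/test sets whose activities are linear in one field.

    The scaffold plus a series of single-site substituents is embedded and
    aligned on the shared ring (MCS) with the fixture seed and fields are
    computed.  Each molecule's activity is 6.0 + signal_sd * t + N(0,
    noise_sd), where t is the standardized score of the molecules on the
    leading principal component of the chosen true field's grid columns — a
    linear function of that field's columns that follows its dominant spatial
    variation, so a noiseless set is recoverable by cross-validated PLS.
    Returns (train, test, truth record).
    """

    n_total = spec.n_train + spec.n_test
    if n_total - 1 > len(spec.substituent_set):
        raise ValueError(
            f"need {n_total - 1} substituents, have {len(spec.substituent_set)}"
        )
    rng = np.random.default_rng(spec.seed)

    from rdkit import Chem

    molecules: list[Molecule] = []
    scaffold_mol = Chem.MolFromSmiles(spec.scaffold)
    if scaffold_mol is None:
        raise ValueError(f"invalid scaffold SMILES {spec.scaffold!r}")
    molecules.append(
        Molecule(name="scaffold", rdmol=scaffold_mol, needs_embedding=True)
    )
    for i, frag in enumerate(spec.substituent_set[: n_total - 1]):
        smiles = frag + spec.scaffold
        rdmol = Chem.MolFromSmiles(smiles)
        if rdmol is None:
            raise ValueError(f"substituent {frag!r} yields invalid SMILES {smiles!r}")
        molecules.append(
            Molecule(name=f"mol_{i:02d}_{frag}", rdmol=rdmol, needs_embedding=True)
        )

    aligned = align_set(MoleculeSet(molecules), seed=spec.seed).aligned
    annotated = annotate_set(aligned)
    grid = build_grid(annotated, spacing=spec.grid_spacing, padding=spec.grid_padding)
    fcfg = FieldConfig(alpha=spec.alpha, fields_enabled=spec.fields_enabled)
    tensor = compute_all_fields(annotated, grid, fcfg)

    fi = tensor.field_names.index(spec.true_field)
    block = tensor.values[:, fi, :]
    centered = block - block.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    loading = vt[0]
    # deterministic sign: largest-magnitude loading positive
    if loading[np.argmax(np.abs(loading))] < 0:
        loading = -loading
    scores = centered @ loading
    t = (scores - scores.mean()) / scores.std()
    activities = 6.0 + spec.signal_sd * t + rng.normal(
        0.0, spec.noise_sd, size=len(annotated)
    )
    top = np.argsort(np.abs(loading))[::-1][:10]

    mols_with_act = [
        Molecule(
            name=m.name, rdmol=m.rdmol, activity=float(a),
            atoms=m.atoms, needs_embedding=False,
        )
        for m, a in zip(annotated, activities)
    ]
    train = MoleculeSet(mols_with_act[: spec.n_train], role="train")
    test = MoleculeSet(mols_with_act[spec.n_train:], role="test")
    truth = FixtureTruth(
        true_field=spec.true_field,
        signal_sd=spec.signal_sd,
        noise_sd=spec.noise_sd,
        seed=spec.seed,
        top_loading_grid_indices=[int(i) for i in top],
        top_loadings=[float(loading[i]) for i in top],
        activities={m.name: float(a) for m, a in zip(annotated, activities)},
    )
    return train, test, truth


def write_fixture(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Generate a fixture and write train/test SDFs plus the truth record."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    train, test, truth = generate_fixture(spec)
    paths = {
        "train": write_sdf(train, out / "train.sdf"),
        "test": write_sdf(test, out / "test.sdf"),
    }
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(asdict(truth), indent=2))
    paths["truth"] = truth_path
    return paths


# ---------------------------------------------------------------------------
# CLI

def main() -> None:  # pragma: no cover - thin click wiring
    import click

    @click.group()
    def cli():
        """Grid-based 3D-QSAR with Gaussian similarity fields."""

    @cli.command("run")
    @click.option("--train", "train_path", required=True, type=click.Path(exists=True))
    @click.option("--test", "test_path", type=click.Path(exists=True))
    @click.option("--predict", "predict_path", type=click.Path(exists=True))
    @click.option("--config", "config_path", type=click.Path(exists=True))
    @click.option("--activity-tag", default=None)
    @click.option("--fields", "fields_enabled", default=None,
                  help="Subset of SEHAD, e.g. SEH")
    @click.option("--spacing", "grid_spacing", type=float, default=None)
    @click.option("--padding", "grid_padding", type=float, default=None)
    @click.option("--alpha", type=float, default=None)
    @click.option("--column-filter", "filter_threshold", type=float, default=None)
    @click.option("--top-fraction", type=float, default=None)
    @click.option("--no-snap", "snap", flag_value=False, default=None)
    @click.option("--align", is_flag=True, default=False)
    @click.option("--template", default=None)
    @click.option("--max-components", type=int, default=None)
    @click.option("--seed", type=int, default=None)
    @click.option("--out", "output_dir", default=None)
    def run_cmd(config_path, **kwargs):
        overrides = {k: v for k, v in kwargs.items() if v is not None}
        if config_path:
            cfg = RunConfig.from_yaml(config_path, **overrides)
        else:
            cfg = RunConfig(**overrides)
        result = run_comsia(cfg)
        click.echo(f"wrote results to {result.output_dir}")
        for k, v in result.metrics.items():
            click.echo(f"{k}: {v:.4f}" if isinstance(v, float) else f"{k}: {v}")

    @cli.command("fixture")
    @click.option("--spec", "spec_path", type=click.Path(exists=True),
                  help="YAML file of FixtureSpec keys")
    @click.option("--seed", type=int, default=0)
    @click.option("--out", "out_dir", default="fixture")
    def fixture_cmd(spec_path, seed, out_dir):
        data = yaml.safe_load(Path(spec_path).read_text()) if spec_path else {}
        data.setdefault("seed", seed)
        paths = write_fixture(FixtureSpec(**data), out_dir)
        for key, path in paths.items():
            click.echo(f"{key}: {path}")

    @cli.command("align")
    @click.option("--smiles", "smiles_path", required=True,
                  type=click.Path(exists=True))
    @click.option("--seed", type=int, default=42)
    @click.option("--template", default=None)
    @click.option("--out", "out_path", default="aligned.sdf")
    def align_cmd(smiles_path, seed, template, out_path):
        mset = read_smiles_table(smiles_path)
        result = align_set(mset, seed=seed, template=template)
        write_sdf(result.aligned, out_path)
        rmsd_path = Path(out_path).with_suffix(".rmsd.tsv")
        with open(rmsd_path, "w") as fh:
            fh.write("molecule\tcore_rmsd\n")
            for name, rmsd in zip(result.aligned.names, result.core_rmsd):
                fh.write(f"{name}\t{rmsd:.4f}\n")
        click.echo(f"aligned set written to {out_path}; core RMSD to {rmsd_path}")

    cli()
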
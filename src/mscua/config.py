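"""Configuration loading, validation and the end-to-end run bundle.

A run is configured by a small YAML file pointing at the three input
tables (parameter registry CSV, model-structure YAML, mortality CSV)
plus run settings, all defaulting to the study conditions (7 annual
cycles, 1000-patient cohorts, 3% discounting, 10,000 PSA iterations).
Validation is not fail-fast: every violation is collected and reported
at once; unknown keys are warned about and ignored.

``run_all`` executes base case, occupancy and cost tables, OWSA,
scenario analyses and PSA with CEAC/CEAF, writing delimited tables plus
a manifest (seed, config hash, package version, stage timings) so a
rerun with the same config and seed reproduces the PSA outputs bitwise.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from . import sensitivity as sa
from .errors import ValidationError
from .valuation import HEALTHCARE_SECTOR, PERSPECTIVES, SOCIETAL

log = logging.getLogger("mscua")

_KNOWN_KEYS = {
    "registry", "structure", "mortality", "perspective", "n_cycles", "n0",
    "psa", "wtp_max", "wtp_points", "output_dir", "owsa_top",
}
_KNOWN_PSA_KEYS = {"n_iter", "seed"}


@dataclass
class ModelConfig:
    registry: Path
    structure: Path
    mortality: Path
    perspective: str = SOCIETAL
    n_cycles: int = 7
    n0: float = 1000.0
    psa_n_iter: int = 10000
    psa_seed: int = 0
    wtp_max: float = 99900.0
    wtp_points: int = 1000
    output_dir: Path = Path("mscua-output")
    source_path: Path | None = None

    def config_hash(self) -> str:
        payload = {k: str(v) for k, v in self.__dict__.items()
                   if k != "source_path"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def load_config(path) -> ModelConfig:
    """Parse and validate a YAML config, collecting every violation."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    errors: list[str] = []
    for key in raw:
        if key not in _KNOWN_KEYS:
            log.warning("unknown config key %r ignored", key)
    for key in ("registry", "structure", "mortality"):
        if key not in raw:
            errors.append(f"missing required path {key!r}")
    psa = raw.get("psa") or {}
    for key in psa:
        if key not in _KNOWN_PSA_KEYS:
            log.warning("unknown psa config key %r ignored", key)

    base = path.parent

    def _path(key):
        p = Path(raw[key])
        return p if p.is_absolute() else base / p

    paths = {}
    for key in ("registry", "structure", "mortality"):
        if key in raw:
            p = _path(key)
            if not p.exists():
                errors.append(f"{key} file not found: {p}")
            paths[key] = p
    persp = raw.get("perspective", SOCIETAL)
    if persp not in PERSPECTIVES:
        errors.append(f"perspective must be one of {PERSPECTIVES}, "
                      f"got {persp!r}")
    n_cycles = int(raw.get("n_cycles", 7))
    if n_cycles < 1:
        errors.append(f"n_cycles must be >= 1, got {n_cycles}")
    n0 = float(raw.get("n0", 1000))
    if n0 <= 0:
        errors.append(f"n0 must be > 0, got {n0}")
    n_iter = int(psa.get("n_iter", 10000))
    if n_iter < 1:
        errors.append(f"psa.n_iter must be >= 1, got {n_iter}")
    if errors:
        raise ValidationError(
            f"invalid configuration ({len(errors)} problems): "
            + "; ".join(errors), errors=errors)
    out_dir = raw.get("output_dir", "mscua-output")
    out_path = Path(out_dir)
    if not out_path.is_absolute():
        out_path = base / out_path
    return ModelConfig(
        registry=paths["registry"], structure=paths["structure"],
        mortality=paths["mortality"], perspective=persp,
        n_cycles=n_cycles, n0=n0,
        psa_n_iter=n_iter, psa_seed=int(psa.get("seed", 0)),
        wtp_max=float(raw.get("wtp_max", 99900.0)),
        wtp_points=int(raw.get("wtp_points", 1000)),
        output_dir=out_path, source_path=path,
    )


def build_model(config: ModelConfig):
    from .model import CostUtilityModel
    model = CostUtilityModel.from_files(
        config.registry, config.structure, config.mortality)
    model.structure.n_cycles = config.n_cycles
    model.structure.n0 = config.n0
    return model


def run_all(config: ModelConfig) -> dict:
    """Run every analysis stage and write the result bundle to disk."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "seed": config.psa_seed,
        "config_hash": config.config_hash(),
        "stages": {},
        "complete": False,
    }
    model = build_model(config)
    wtp = sa.default_wtp_grid(config.wtp_max, config.wtp_points)

    def _stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            manifest["stages"][name] = {"status": "failed",
                                        "error": str(exc)}
            _write_manifest(out, manifest)
            raise ValidationError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {
            "status": "ok",
            "seconds": round(time.perf_counter() - t0, 3)}
        log.info("stage %s done in %.2fs", name,
                 time.perf_counter() - t0)
        return result

    results = _stage("basecase", model.fit)
    results.cua_table().to_csv(out / "cua.csv", index=False)
    results.cost_table().to_csv(out / "costs.csv")
    for strat in ("naive", "experienced"):
        results.occupancy_table(strat).to_csv(out / f"occupancy_{strat}.csv")

    owsa = _stage("owsa", lambda: results.run_owsa(config.perspective))
    owsa.to_csv(out / "owsa.csv", index=False)

    yearly = _stage("yearly_icur",
                    lambda: results.yearly_icur(config.perspective))
    yearly.to_csv(out / "yearly_icur.csv", index=False)
    adher = _stage("scenario_adherence",
                   lambda: sa.scenario_adherence(
                       model, perspective=config.perspective))
    adher.to_csv(out / "scenario_adherence.csv", index=False)
    remis = _stage("scenario_remission",
                   lambda: sa.scenario_remission(
                       model, perspective=config.perspective))
    remis.to_csv(out / "scenario_remission.csv", index=False)

    psa = _stage("psa", lambda: results.run_psa(
        n_iter=config.psa_n_iter, seed=config.psa_seed))
    psa.to_frame().to_csv(out / "psa_samples.csv", index=False)
    manifest["psa_resampled"] = psa.n_resampled
    for persp in PERSPECTIVES:
        sa.ceac(psa, wtp, persp).to_csv(
            out / f"ceac_{persp}.csv", index=False)
        sa.ceaf(psa, wtp, persp).to_csv(
            out / f"ceaf_{persp}.csv", index=False)

    manifest["complete"] = True
    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict):
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def write_synthetic_bundle(out_dir, seed: int = 0, spec=None) -> dict:
    """Generate a synthetic registry/structure/mortality trio plus a
    ready-to-run config file."""
    from .synthetic import SyntheticScenarioSpec, generate_registry
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = generate_registry(spec or SyntheticScenarioSpec(seed=seed))
    bundle.registry.to_csv(out / "registry.csv")
    bundle.structure.to_yaml(out / "structure.yaml")
    bundle.structure.mortality.to_csv(out / "mortality.csv")
    config = {
        "registry": "registry.csv",
        "structure": "structure.yaml",
        "mortality": "mortality.csv",
        "perspective": SOCIETAL,
        "n_cycles": bundle.structure.n_cycles,
        "n0": bundle.structure.n0,
        "psa": {"n_iter": 10000, "seed": seed},
        "output_dir": "output",
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return config
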
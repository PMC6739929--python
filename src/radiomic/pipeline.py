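"""End-to-end orchestration: simulate -> extract -> select -> classify.

A run is driven by a single YAML config and a top-level seed, producing a
run directory with the resolved config, the manifest, the feature table,
one frozen feature-set JSON per (criterion, pair), and one classification
report JSON per (criterion, pair).  Reruns with an identical config are
bit-identical apart from log timestamps.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as rio
from .classify import frozen_evaluate, knn_loocv, _restrict
from .extract import extract_cohort
from .selection import CRITERIA, select
from .synthetic import SyntheticCohortSpec, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one pipeline run."""

    out_dir: str
    manifest: str | None = None
    synthetic: SyntheticCohortSpec | None = None
    n_levels: int = 64
    methods: tuple[str, ...] = CRITERIA
    pairs: str | tuple[tuple[str, str], ...] = "all"
    knn: int = 1
    seed: int = 0

    def __post_init__(self):
        if (self.manifest is None) == (self.synthetic is None):
            raise ValueError("config needs exactly one of manifest / synthetic")
        bad = [m for m in self.methods if m not in CRITERIA]
        if bad:
            raise ValueError(f"unknown selection method(s): {bad}")

    @classmethod
    def from_yaml(cls, path, out_dir=None, seed=None) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if out_dir is not None:
            raw["out_dir"] = str(out_dir)
        if seed is not None:
            raw["seed"] = int(seed)
        syn = raw.pop("synthetic", None)
        if syn is not None:
            recipes = syn.pop("recipes")
            n_per_class = tuple(int(n) for n in syn.pop("n_per_class"))
            from .synthetic import ClassRecipe

            syn = SyntheticCohortSpec(
                recipes=tuple(ClassRecipe(**r) for r in recipes),
                n_per_class=n_per_class,
                seed=int(raw.get("seed", 0)),
                **syn,
            )
        methods = tuple(raw.pop("methods", CRITERIA))
        pairs = raw.pop("pairs", "all")
        if pairs != "all":
            pairs = tuple((str(a), str(b)) for a, b in pairs)
        return cls(synthetic=syn, methods=methods, pairs=pairs, **raw)

    def resolved(self) -> dict:
        d = {
            "out_dir": self.out_dir,
            "manifest": self.manifest,
            "n_levels": self.n_levels,
            "methods": list(self.methods),
            "pairs": "all" if self.pairs == "all" else [list(p) for p in self.pairs],
            "knn": self.knn,
            "seed": self.seed,
        }
        if self.synthetic is not None:
            d["synthetic"] = {
                "recipes": [vars(r) | {} for r in self.synthetic.recipes],
                "n_per_class": list(self.synthetic.n_per_class),
                "image_size": self.synthetic.image_size,
                "background_level": self.synthetic.background_level,
                "background_noise_sd": self.synthetic.background_noise_sd,
                "seed": self.synthetic.seed,
            }
        return d


def _all_pairs(classes: list[str]) -> list[tuple[str, str]]:
    pairs = list(itertools.combinations(classes, 2))
    if len(classes) > 2:
        pairs += [(c, "rest") for c in classes]
    return pairs


def _safe(name: str) -> str:
    return "".join(ch if ch.isalnum() else "_" for ch in name)


def run_pipeline(config: RunConfig) -> Path:
    """Execute all pipeline stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.resolved.yaml", "w") as fh:
        yaml.safe_dump(config.resolved(), fh, sort_keys=True)

    stage = "simulate"
    try:
        if config.synthetic is not None:
            spec = config.synthetic
            if spec.seed != config.seed:
                spec = SyntheticCohortSpec(
                    recipes=spec.recipes,
                    n_per_class=spec.n_per_class,
                    image_size=spec.image_size,
                    background_level=spec.background_level,
                    background_noise_sd=spec.background_noise_sd,
                    seed=config.seed,
                )
            manifest = generate_cohort(spec, out / "cohort")
        else:
            manifest = rio.read_manifest(config.manifest)

        stage = "extract"
        features = extract_cohort(manifest, n_levels=config.n_levels)
        rio.write_feature_table(features, out / "features.csv")

        labels = manifest["subtype"].to_numpy()
        classes = sorted(set(labels))
        pairs = _all_pairs(classes) if config.pairs == "all" else list(config.pairs)

        for method in config.methods:
            for pair in pairs:
                stage = f"select[{method}:{pair}]"
                sel = select(features, labels, method, pair)
                tag = f"{method}_{_safe(pair[0])}_vs_{_safe(pair[1])}"
                rio.write_feature_set(sel.to_dict(), out / f"set_{tag}.json")
                stage = f"classify[{method}:{pair}]"
                sub, y = _restrict(features, labels, pair)
                rep = knn_loocv(
                    sub,
                    y,
                    sel.features,
                    k_neighbors=config.knn,
                    pair=pair,
                    criterion=method,
                )
                with open(out / f"report_{tag}.json", "w") as fh:
                    json.dump(rep.to_dict(), fh, indent=1, sort_keys=True)
    except Exception as exc:  # pragma: no cover - error path formatting
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out


def validate_with_frozen_sets(run_dir, validation_features, validation_labels, knn=1):
    """Apply every frozen feature set of a run to a validation cohort."""
    run_dir = Path(run_dir)
    results = {}
    for path in sorted(run_dir.glob("set_*.json")):
        fs = rio.read_feature_set(path)
        pair = tuple(fs["pair"])
        labels = np.asarray(validation_labels)
        mask_a = labels == pair[0]
        mask_b = ~mask_a if pair[1] == "rest" else labels == pair[1]
        keep = mask_a | mask_b
        if mask_a.sum() < 2 or mask_b.sum() < 2:
            continue
        y = np.where(mask_a[keep], pair[0], pair[1])
        rep = frozen_evaluate(
            validation_features.loc[keep].reset_index(drop=True), y, fs, k_neighbors=knn
        )
        results[path.stem] = rep
    return results
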
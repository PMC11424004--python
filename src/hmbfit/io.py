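"""Readers, writers and bundled example data.

Tables are UTF-8 comma-delimited text with a mandatory header; results
bundles are a deterministic set of CSV files plus a JSON manifest
carrying the seed, configuration and a content hash, sufficient to
re-run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data import RateDataset
from .errors import ValidationError

__all__ = ["read_rate_table", "ResultBundle", "write_results", "read_results", "make_fixtures"]

_COLUMN_ALIASES = {
    "time": ("time", "t", "interval", "age"),
    "rate": ("rate", "r"),
    "numerator": ("numerator", "change", "amount"),
    "denominator": ("denominator",),
    "dataset": ("dataset", "group"),
}


def _resolve_columns(df: pd.DataFrame, column_map: dict | None) -> dict:
    resolved = dict(column_map or {})
    lower = {c.lower(): c for c in df.columns}
    for key, aliases in _COLUMN_ALIASES.items():
        if key in resolved:
            continue
        for alias in aliases:
            if alias in lower:
                resolved[key] = lower[alias]
                break
    return resolved


def read_rate_table(
    path: str | Path,
    column_map: dict | None = None,
    dataset: str | None = None,
    sep: str = ",",
    **dataset_kwargs,
) -> RateDataset:
    """Load a delimited rate table into a validated dataset.

    Requires ``time`` and ``rate`` columns (a ``column_map`` can point
    nonstandard names at them); ``numerator`` is imputed as
    rate * time when absent.  Rows with non-positive times or negative
    rates are rejected with their line number.  When a ``dataset``
    grouping column is present, pass ``dataset=`` to pick one group.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    df = pd.read_csv(path, sep=sep)
    cols = _resolve_columns(df, column_map)
    for required in ("time", "rate"):
        if required not in cols:
            raise ValidationError(
                f"{path.name}: required column {required!r} not found "
                f"(have: {list(df.columns)})"
            )
    if "dataset" in cols:
        groups = df[cols["dataset"]].unique().tolist()
        if dataset is not None:
            if dataset not in groups:
                raise ValidationError(f"{path.name}: no dataset group {dataset!r}")
            df = df[df[cols["dataset"]] == dataset]
        elif len(groups) > 1:
            raise ValidationError(
                f"{path.name}: multiple dataset groups {groups}; pass dataset="
            )
    time = pd.to_numeric(df[cols["time"]], errors="coerce")
    rate = pd.to_numeric(df[cols["rate"]], errors="coerce")
    for label, series, check in (
        ("time", time, lambda s: (s.isna()) | (s <= 0)),
        ("rate", rate, lambda s: (s.isna()) | (s < 0)),
    ):
        bad = check(series)
        if bad.any():
            # +2: header line plus 1-based numbering
            line = int(df.index[bad.to_numpy()][0]) + 2
            raise ValidationError(f"{path.name}: invalid {label} value at line {line}")
    numerator = (
        pd.to_numeric(df[cols["numerator"]], errors="coerce").to_numpy(float)
        if "numerator" in cols
        else None
    )
    denominator = (
        pd.to_numeric(df[cols["denominator"]], errors="coerce").to_numpy(float)
        if "denominator" in cols
        else None
    )
    if numerator is not None and np.isnan(numerator).any():
        denom = denominator if denominator is not None else time.to_numpy(float)
        missing = np.isnan(numerator)
        numerator[missing] = rate.to_numpy(float)[missing] * denom[missing]
    return RateDataset(
        time=time.to_numpy(float),
        rate=rate.to_numpy(float),
        numerator=numerator,
        denominator=denominator,
        name=dataset or path.stem,
        **dataset_kwargs,
    )


@dataclass
class ResultBundle:
    """Everything one analysis run produced, ready to serialize."""

    seed: int
    config: dict = field(default_factory=dict)
    fit_table: pd.DataFrame | None = None
    region: pd.DataFrame | None = None
    contributions: pd.DataFrame | None = None
    comparison: pd.DataFrame | None = None
    pvalues: dict | None = None
    simulation: pd.DataFrame | None = None

    _FRAME_SECTIONS = ("fit_table", "region", "contributions", "comparison", "simulation")


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def write_results(bundle: ResultBundle, prefix: str | Path) -> list[Path]:
    """Write the bundle as CSV files plus a JSON manifest.

    Empty optional sections are omitted; the manifest lists what
    exists.  Returns the written paths (manifest last).
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    sections: dict[str, str] = {}
    for section in ResultBundle._FRAME_SECTIONS:
        frame = getattr(bundle, section)
        if frame is None or len(frame) == 0:
            continue
        path = prefix.parent / f"{prefix.name}_{section}.csv"
        frame.to_csv(path, index=False)
        written.append(path)
        sections[section] = path.name
    manifest = {
        "package": "hmbfit",
        "version": __version__,
        "seed": bundle.seed,
        "config": bundle.config,
        "config_hash": _config_hash(bundle.config),
        "sections": sections,
        "pvalues": bundle.pvalues,
    }
    manifest_path = prefix.parent / f"{prefix.name}_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(manifest_path)
    return written


def read_results(prefix: str | Path) -> ResultBundle:
    """Reconstruct a bundle from its manifest; inverse of write_results."""
    prefix = Path(prefix)
    manifest_path = prefix.parent / f"{prefix.name}_manifest.json"
    if not manifest_path.exists():
        raise ValidationError(f"no manifest at {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    bundle = ResultBundle(seed=manifest["seed"], config=manifest["config"])
    bundle.pvalues = manifest.get("pvalues")
    for section, filename in manifest["sections"].items():
        setattr(bundle, section, pd.read_csv(prefix.parent / filename))
    return bundle


def make_fixtures(seed: int = 0) -> dict:
    """Small bundled example datasets, fully determined by the seed.

    Returns a dict with:

    - ``"paired"``: 200 paired-comparison rates whose numerators carry
      time-independent Gaussian noise on top of a weak linear trend
      (m = 0.002, b = 0.05, noise sd 0.5), so the fitted model should
      attribute a hyperbolic component;
    - ``"yule"``: a 500-tree pure-birth study table (both estimators);
    - ``"mk_newick"`` / ``"mk_states"``: a balanced 64-tip tree of age
      10 Myr with simulated two-state characters at 0.05 transitions/Myr.
    """
    from .mk import build_tree, simulate_mk
    from .yule import YuleStudyConfig, run_yule_study

    ss = np.random.SeedSequence(seed)
    s_paired, s_yule, s_mk = ss.spawn(3)

    rng = np.random.default_rng(s_paired)
    t = np.exp(rng.uniform(np.log(0.1), np.log(60.0), 200))
    m_true, b_true, noise_sd = 0.002, 0.05, 0.5
    numerator = np.abs((m_true * t + b_true) * t + rng.normal(0.0, noise_sd, t.size))
    paired = pd.DataFrame({"time": t, "rate": numerator / t, "numerator": numerator})

    yule = run_yule_study(
        YuleStudyConfig(n_trees=500, seed=int(s_yule.generate_state(1)[0] % 2**31))
    )

    tree = build_tree("balanced", n_tips=64, age=10.0)
    states = simulate_mk(tree, 0.05, np.random.default_rng(s_mk))
    return {
        "paired": paired,
        "yule": yule,
        "mk_newick": tree.to_newick(),
        "mk_states": states.to_frame(tree),
        "truth": {"paired": {"m": m_true, "b": b_true, "noise_sd": noise_sd}},
    }


def write_fixtures(out_dir: str | Path, seed: int = 0) -> list[Path]:
    """Write the bundled fixtures to disk as plain text."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fx = make_fixtures(seed)
    written = []
    for name in ("paired", "yule", "mk_states"):
        path = out / f"{name}.csv"
        fx[name].to_csv(path, index=False)
        written.append(path)
    tree_path = out / "mk_tree.nwk"
    tree_path.write_text(fx["mk_newick"] + "\n")
    written.append(tree_path)
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps({"seed": seed, **fx["truth"]}, indent=2) + "\n")
    written.append(truth_path)
    return written
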
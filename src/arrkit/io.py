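"""Series CSV I/O, study configuration, and the end-to-end study runner.

The series dialect is a CSV with header columns ``clade,age_ma,richness``
(one clade per file, or several multiplexed through the ``clade`` column).
Per-clade metadata -- stem age, rescaling mode, calibration richness --
lives in a YAML or JSON study configuration, not in the series files.

``run_study`` executes the full empirical workflow for every clade and
extinction fraction: rescale -> ARR through time -> all lagged pairs ->
lag bins -> support summary -> rate decline factors, writing ``rates.csv``,
``pairs.csv``, ``bins.csv``, ``support.csv``, and a run manifest.  Given a
seed the outputs are byte-identical across reruns.
"""

from __future__ import annotations

import json
import logging
import sys
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .pipeline import (
    DiversitySeries,
    analyze_pairs,
    arr_through_time,
    bin_by_lag,
    pairs_to_frame,
    rate_decline_factor,
    rescale_series,
    summarize_support,
)

__all__ = [
    "CladeSpec",
    "StudyConfig",
    "read_series_csv",
    "write_series_csv",
    "run_study",
]

logger = logging.getLogger("arrkit")

SERIES_COLUMNS = ("clade", "age_ma", "richness")


def read_series_csv(
    path: str | Path,
    *,
    clade: str | None = None,
    stem_age_ma: float,
    rescale_mode: str = "none",
    calibration_richness: float | None = None,
) -> DiversitySeries:
    """Read one clade's raw diversity series from CSV.

    ``clade`` selects one clade from a multiplexed file; omit it when the
    file holds a single clade.  Rows are sorted oldest-first on load.
    Malformed rows (non-numeric fields, duplicate ages) are reported with
    their line numbers; ages at or beyond the stem age fail validation.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; header must be {SERIES_COLUMNS}")
    # header is line 1, first data row line 2
    df["_line"] = df.index + 2
    if clade is not None:
        df = df[df["clade"] == clade]
        if df.empty:
            raise ValueError(f"{path}: no rows for clade {clade!r}")
    else:
        clades = df["clade"].unique()
        if len(clades) != 1:
            raise ValueError(
                f"{path}: file multiplexes clades {sorted(clades)}; pass clade= to select one"
            )
        clade = clades[0]
    bad_lines = []
    for col in ("age_ma", "richness"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad_lines.extend(df.loc[numeric.isna(), "_line"].tolist())
        df[col] = numeric
    if bad_lines:
        raise ValueError(f"{path}: non-numeric age_ma/richness on line(s) {sorted(set(bad_lines))}")
    dup = df[df.duplicated("age_ma", keep=False)]
    if not dup.empty:
        raise ValueError(
            f"{path}: duplicate age_ma values for clade {clade!r} on lines "
            f"{sorted(dup['_line'].tolist())}"
        )
    df = df.sort_values("age_ma", ascending=False)
    return DiversitySeries(
        clade=clade,
        stem_age_ma=stem_age_ma,
        ages_ma=df["age_ma"].to_numpy(),
        raw_richness=df["richness"].to_numpy(),
        rescale_mode=rescale_mode,
        calibration_richness=calibration_richness,
    )


def write_series_csv(series: DiversitySeries, path: str | Path) -> None:
    """Write a series in the input dialect (raw richness; lossless
    round-trip for the declared columns)."""
    pd.DataFrame(
        {"clade": series.clade, "age_ma": series.ages_ma, "richness": series.raw_richness}
    ).to_csv(path, index=False)


@dataclass
class CladeSpec:
    """Where one clade's series lives and how to rescale it."""

    path: str
    stem_age_ma: float
    clade: str | None = None
    rescale_mode: str = "none"
    calibration_richness: float | None = None


@dataclass
class StudyConfig:
    """Configuration of a full multi-clade study run."""

    clades: list[CladeSpec]
    epsilons: list[float] = field(default_factory=lambda: [0.5, 0.9])
    bin_width_my: float = 15.0
    support_threshold: float = 0.95
    seed: int = 0
    random_draws: int = 200
    output_dir: str = "arr_study_output"

    def __post_init__(self) -> None:
        if not all(0.0 <= e < 1.0 for e in self.epsilons):
            raise ValueError(f"epsilons must lie in [0, 1), got {self.epsilons}")
        if self.bin_width_my <= 0:
            raise ValueError("bin_width_my must be > 0")
        if not 0.5 < self.support_threshold < 1.0:
            raise ValueError("support_threshold must be in (0.5, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        path = Path(path)
        text = path.read_text()
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        clades = [CladeSpec(**c) for c in raw.pop("clades")]
        cfg = cls(clades=clades, **raw)
        # series paths are relative to the config file
        for spec in cfg.clades:
            if not Path(spec.path).is_absolute():
                spec.path = str(path.parent / spec.path)
        return cfg


def _load_clade(spec: CladeSpec) -> DiversitySeries:
    series = read_series_csv(
        spec.path,
        clade=spec.clade,
        stem_age_ma=spec.stem_age_ma,
        rescale_mode=spec.rescale_mode,
        calibration_richness=spec.calibration_richness,
    )
    return rescale_series(series.truncate_extinct())


def run_study(config: StudyConfig) -> dict:
    """Run the full pipeline for every clade x extinction fraction and
    write rates/pairs/bins/support CSVs plus a run manifest.

    Per-clade failures are logged and skipped rather than aborting the
    batch; the returned dict lists them under ``"skipped"`` (the CLI turns
    a non-empty list into a non-zero exit).  Pooled and per-clade support
    summaries are both emitted.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    root_seq = np.random.SeedSequence(config.seed)

    rates_frames, pairs_all, skipped = [], {}, []
    for spec in config.clades:
        name = spec.clade or spec.path
        try:
            series = _load_clade(spec)
            if len(series) < 2:
                raise ValueError(f"{series.clade}: need >= 2 timepoints, got {len(series)}")
        except Exception as exc:  # noqa: BLE001 - per-clade isolation is the contract
            logger.warning("skipping clade %s: %s", name, exc)
            skipped.append({"clade": name, "error": str(exc)})
            continue
        logger.info("analyzing clade %s (%d timepoints)", series.clade, len(series))
        for k, eps in enumerate(config.epsilons):
            rates = arr_through_time(series, eps)
            rates.insert(0, "clade", series.clade)
            rates.insert(4, "epsilon", eps)
            rates_frames.append(rates)
            # deterministic child seed per (clade, eps); crc32 is stable
            # across processes, unlike the builtin str hash
            child = np.random.SeedSequence(
                entropy=root_seq.entropy,
                spawn_key=(zlib.crc32(series.clade.encode()), k),
            )
            pairs_all.setdefault(eps, []).extend(
                analyze_pairs(
                    series,
                    eps,
                    seed=np.random.default_rng(child),
                    random_draws=config.random_draws,
                )
            )

    rates_df = pd.concat(rates_frames, ignore_index=True) if rates_frames else pd.DataFrame()
    pairs_frames, bins_frames, support_frames, decline_rows = [], [], [], []
    for eps, results in pairs_all.items():
        pf = pairs_to_frame(results)
        pairs_frames.append(pf)
        bins = bin_by_lag(results, config.bin_width_my)
        bins.insert(0, "epsilon", eps)
        bins_frames.append(bins)
        pooled = summarize_support(results, hi=config.support_threshold)
        pooled.insert(0, "clade", "ALL")
        pooled.insert(0, "epsilon", eps)
        support_frames.append(pooled)
        for clade_name in pf["clade"].unique():
            per = summarize_support(
                [p for p in results if p.clade == clade_name], hi=config.support_threshold
            )
            per.insert(0, "clade", clade_name)
            per.insert(0, "epsilon", eps)
            support_frames.append(per)
    if not rates_df.empty:
        for (clade_name, eps), grp in rates_df.groupby(["clade", "epsilon"], sort=True):
            decline_rows.append(
                {"clade": clade_name, "epsilon": eps, "rate_decline_factor": rate_decline_factor(grp)}
            )

    pairs_df = pd.concat(pairs_frames, ignore_index=True) if pairs_frames else pd.DataFrame()
    bins_df = pd.concat(bins_frames, ignore_index=True) if bins_frames else pd.DataFrame()
    support_df = pd.concat(support_frames, ignore_index=True) if support_frames else pd.DataFrame()
    decline_df = pd.DataFrame(decline_rows)

    rates_df.to_csv(out / "rates.csv", index=False)
    pairs_df.to_csv(out / "pairs.csv", index=False)
    bins_df.to_csv(out / "bins.csv", index=False)
    support_df.to_csv(out / "support.csv", index=False)
    decline_df.to_csv(out / "decline.csv", index=False)
    manifest = {
        "arrkit_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "epsilons": config.epsilons,
        "bin_width_my": config.bin_width_my,
        "support_threshold": config.support_threshold,
        "random_draws": config.random_draws,
        "clades": [vars(c) for c in config.clades],
        "skipped": skipped,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return {
        "rates": rates_df,
        "pairs": pairs_df,
        "bins": bins_df,
        "support": support_df,
        "decline": decline_df,
        "skipped": skipped,
        "output_dir": out,
    }


def setup_logging(verbose: bool = True) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if verbose else logging.WARNING,
        format="%(levelname)s %(name)s: %(message)s",
    )
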
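"""File plumbing: read joint-model summary files, write derived statistics.

Input files are tab-delimited with a header, one row per variant, in the
dialect produced by meta-analysis of joint GxE screens (METAL interaction
output lineage). Column names are remappable because consortium files vary;
gzipped input is read transparently. Output is a single tab-delimited file
with the derived unexposed / exposed / marginal statistics per variant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .estimators import derive_frame, sample_size_threshold
from .records import (ConfigurationError, JointRecord, StudyDesign,
                      ValidationError)

logger = logging.getLogger("jointstrat")

#: Role -> default header name (METAL interaction-analysis naming lineage).
DEFAULT_COLUMNS: dict[str, str] = {
    "variant_id": "MarkerName",
    "beta": "Effect",
    "se_beta": "StdErr",
    "delta": "IntEffect",
    "se_delta": "IntStdErr",
    "corr": "IntCor",
    "n_variant": "N",
}

#: Optional roles: absent from the file unless explicitly mapped/present.
OPTIONAL_ROLES = ("corr", "cov")

OUTPUT_COLUMNS = [
    "variant_id",
    "n_unexp", "beta_unexp", "se_unexp", "z_unexp", "p_unexp",
    "n_exp", "beta_exp", "se_exp", "z_exp", "p_exp",
    "n_marg", "beta_marg", "se_marg", "z_marg", "p_marg",
    "filtered",
]

_MAX_ROW_WARNINGS = 10


@dataclass(frozen=True)
class RunConfig:
    """One derivation run: paths, design, column mapping, filter policy."""

    input_path: Path
    output_path: Path
    n_total: int
    n_exposed: int
    column_map: Mapping[str, str] = field(default_factory=dict)
    keep_filtered: bool = False
    no_filter: bool = False
    log_path: Path | None = None

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ConfigurationError(f"n_total must be > 0, got {self.n_total}")
        if not 0 <= self.n_exposed <= self.n_total:
            raise ConfigurationError(
                f"n_exposed must lie in [0, n_total], got {self.n_exposed}")

    @property
    def design(self) -> StudyDesign:
        return StudyDesign(n_total=self.n_total, n_exposed=self.n_exposed)

    def resolved_columns(self) -> dict[str, str]:
        cols = dict(DEFAULT_COLUMNS)
        for role, name in self.column_map.items():
            if role not in DEFAULT_COLUMNS and role not in OPTIONAL_ROLES:
                raise ConfigurationError(
                    f"unknown column role {role!r}; valid roles: "
                    f"{sorted(set(DEFAULT_COLUMNS) | set(OPTIONAL_ROLES))}")
            cols[role] = name
        return cols


@dataclass(frozen=True)
class PipelineSummary:
    """Row accounting for one run: read = written + dropped + hard_invalid."""

    n_read: int
    n_hard_invalid: int
    n_soft_invalid: int
    n_filtered: int
    n_written: int
    threshold: float


def read_joint_frame(path: str | Path,
                     column_map: Mapping[str, str] | None = None,
                     ) -> pd.DataFrame:
    """Read a summary file into the canonical column layout.

    Returns a DataFrame with columns ``variant_id, beta, se_beta, delta,
    se_delta, corr_beta_delta, cov_beta_delta, n_variant, valid, filtered``
    plus any passthrough columns. Rows with out-of-range finite values
    (|corr| > 1, negative SE) have the offending fields set to NaN and
    ``valid`` set False; they are not dropped here.
    """
    path = Path(path)
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        for role, name in column_map.items():
            cols[role] = name
    try:
        raw = pd.read_csv(path, sep="\t", compression="infer")
    except OSError as exc:
        raise ConfigurationError(f"cannot read {path}: {exc}") from exc

    required = {r: n for r, n in cols.items() if r != "cov"}
    has_cov = "cov" in cols and cols["cov"] in raw.columns
    if has_cov:
        required.pop("corr", None)  # covariance column stands in for corr
    missing = [n for n in required.values() if n not in raw.columns]
    if missing:
        raise ConfigurationError(
            f"missing required column(s) {missing} in {path.name}; "
            f"header found: {list(raw.columns)}")

    out = pd.DataFrame(index=raw.index)
    out["variant_id"] = raw[cols["variant_id"]].astype(str)
    for role, dest in (("beta", "beta"), ("se_beta", "se_beta"),
                       ("delta", "delta"), ("se_delta", "se_delta"),
                       ("n_variant", "n_variant")):
        out[dest] = pd.to_numeric(raw[cols[role]], errors="coerce")
    if cols.get("corr") in raw.columns:
        out["corr_beta_delta"] = pd.to_numeric(raw[cols["corr"]],
                                               errors="coerce")
    else:
        out["corr_beta_delta"] = np.nan
    if has_cov:
        out["cov_beta_delta"] = pd.to_numeric(raw[cols["cov"]],
                                              errors="coerce")
    else:
        out["cov_beta_delta"] = np.nan

    valid = np.ones(len(out), dtype=bool)
    bad_corr = out["corr_beta_delta"].abs() > 1
    if bad_corr.any():
        for vid in out.loc[bad_corr, "variant_id"].head(_MAX_ROW_WARNINGS):
            logger.warning("variant %s: correlation outside [-1, 1]; "
                           "derived statistics set to NA", vid)
        out.loc[bad_corr, "corr_beta_delta"] = np.nan
        valid &= ~bad_corr.to_numpy()
    for col in ("se_beta", "se_delta"):
        bad = out[col] < 0
        if bad.any():
            for vid in out.loc[bad, "variant_id"].head(_MAX_ROW_WARNINGS):
                logger.warning("variant %s: negative %s; derived statistics "
                               "set to NA", vid, col)
            out.loc[bad, col] = np.nan
            valid &= ~bad.to_numpy()
    out["valid"] = valid
    out["filtered"] = False

    mapped = set(cols.values())
    for name in raw.columns:
        if name not in mapped:
            out[name] = raw[name]
    return out


def read_joint_file(path: str | Path,
                    column_map: Mapping[str, str] | None = None,
                    ) -> list[JointRecord]:
    """Read a summary file as a list of JointRecord.

    Rows with invalid values are returned with the offending fields as NaN
    (missing sentinels) rather than dropped; rows with an unusable sample
    size are skipped with a warning, because no record can represent them.
    """
    frame = read_joint_frame(path, column_map)
    canonical = {"variant_id", "beta", "se_beta", "delta", "se_delta",
                 "corr_beta_delta", "cov_beta_delta", "n_variant", "valid",
                 "filtered"}
    passthrough = [c for c in frame.columns if c not in canonical]
    records: list[JointRecord] = []
    for row in frame.itertuples(index=False):
        d = row._asdict()
        try:
            records.append(JointRecord(
                variant_id=d["variant_id"],
                beta=d["beta"], se_beta=d["se_beta"],
                delta=d["delta"], se_delta=d["se_delta"],
                n_variant=d["n_variant"],
                corr_beta_delta=d["corr_beta_delta"],
                cov_beta_delta=d["cov_beta_delta"],
                extras={k: d[k] for k in passthrough},
            ))
        except ValidationError as exc:
            logger.warning("skipping row: %s", exc)
    return records


def _format_value(x: object) -> str:
    if isinstance(x, (bool, np.bool_)):
        return "1" if x else "0"
    if isinstance(x, (float, np.floating)):
        if math.isnan(x):
            return "NA"
        return f"{x:.6g}"
    return str(x)


def write_derived(frame: pd.DataFrame, path: str | Path) -> None:
    """Write the derived-statistics table (6 significant digits, NA for missing)."""
    cols = [c for c in OUTPUT_COLUMNS if c in frame.columns]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in frame[cols].itertuples(index=False):
            fh.write("\t".join(_format_value(v) for v in row) + "\n")


def run_pipeline(config: RunConfig) -> PipelineSummary:
    """Full run: read, validate, filter by relative sample size, derive, write.

    Rows without a usable per-variant sample size cannot be filtered or
    sized and are dropped (hard-invalid, counted); rows with missing or
    out-of-range effect fields are written with NA statistics
    (soft-invalid, counted). By default, variants flagged by the
    9th-decile/1.5 rule are excluded from the output file.
    """
    design = config.design
    design.require_two_strata()

    frame = read_joint_frame(config.input_path, config.resolved_columns()
                             if config.column_map else None)
    n_read = len(frame)
    if n_read == 0:
        raise ValidationError(f"no records in {config.input_path}")

    usable_n = np.isfinite(frame["n_variant"].to_numpy(float)) \
        & (frame["n_variant"].to_numpy(float) > 0)
    n_hard = int((~usable_n).sum())
    if n_hard:
        logger.warning("%d row(s) dropped: missing or non-positive sample size",
                       n_hard)
    frame = frame.loc[usable_n].reset_index(drop=True)
    if len(frame) == 0:
        raise ValidationError("no records with a usable sample size")

    if config.no_filter:
        threshold = math.nan
    else:
        threshold = sample_size_threshold(frame["n_variant"])
        frame["filtered"] = frame["n_variant"].to_numpy(float) < threshold
    n_filtered = int(frame["filtered"].sum())

    out_frame = frame if config.keep_filtered else \
        frame.loc[~frame["filtered"]].reset_index(drop=True)
    derived = derive_frame(out_frame, design)
    write_derived(derived, config.output_path)

    n_soft = int((~frame["valid"]).sum())
    summary = PipelineSummary(
        n_read=n_read, n_hard_invalid=n_hard, n_soft_invalid=n_soft,
        n_filtered=n_filtered, n_written=len(derived), threshold=threshold)
    logger.info(
        "read %d rows: %d written, %d excluded by sample-size filter, "
        "%d unusable, %d with missing statistics (threshold %.6g)",
        summary.n_read, summary.n_written, 0 if config.keep_filtered
        else summary.n_filtered, summary.n_hard_invalid,
        summary.n_soft_invalid, threshold)
    return summary
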
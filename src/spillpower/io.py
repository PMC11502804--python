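"""Table I/O, run configuration and publication-style table assembly."""

from __future__ import annotations

import hashlib
import io as _io
import json
import pathlib
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .estimation import bh_adjust
from .experiment import EXPERIMENT_COLUMNS, validate_experiment_table
from .results import CoefficientEstimate, ModeratedDecomposition, SpilloverDecomposition

__all__ = [
    "read_table",
    "write_table",
    "render_results_table",
    "load_config",
    "EmptyInputError",
]

SIMULATED_COLUMNS = ("T", "IV", "U1", "PEB1", "U2", "PEB2")


class EmptyInputError(ValueError):
    """An input table has no rows."""


def read_table(path: str | pathlib.Path, schema: str = "experiment") -> pd.DataFrame:
    """Load and validate a CSV in the simulated or experiment schema.

    Provenance header lines starting with ``#`` are skipped; row order is
    preserved.  Schema violations raise ``ValueError`` naming the row and
    column.
    """
    path = pathlib.Path(path)
    df = pd.read_csv(path, comment="#")
    if df.empty:
        raise EmptyInputError(f"{path}: empty input table")
    if schema == "experiment":
        validate_experiment_table(df)
    elif schema == "simulated":
        missing = set(SIMULATED_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"missing simulated columns: {sorted(missing)}")
        for col in ("T", "IV"):
            bad = ~df[col].isin([0, 1])
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise ValueError(f"row {row}: {col} must be binary")
    else:
        raise ValueError("schema must be 'experiment' or 'simulated'")
    return df


def write_table(
    df: pd.DataFrame,
    path: str | pathlib.Path,
    seed: int | None = None,
    config: Mapping | None = None,
) -> None:
    """Write a CSV with a provenance header comment (version, config hash, seed)."""
    from . import __version__

    digest = "none"
    if config is not None:
        blob = json.dumps(config, sort_keys=True, default=str).encode()
        digest = hashlib.sha256(blob).hexdigest()[:12]
    header = f"# spillpower {__version__} seed={seed} config_sha256={digest}\n"
    buf = _io.StringIO()
    df.to_csv(buf, index=False)
    pathlib.Path(path).write_text(header + buf.getvalue())


def _coefficient_rows(contrast: str, estimates: Iterable[CoefficientEstimate]):
    for est in estimates:
        yield contrast, est.name, "estimate", est.value
        yield contrast, est.name, "robust_se", est.robust_se
        yield contrast, est.name, "p_raw", est.p_two_sided
        yield contrast, est.name, "ci_low", est.ci95[0]
        yield contrast, est.name, "ci_high", est.ci95[1]


def render_results_table(
    estimates: Sequence[tuple[str, object]],
    layout: str,
) -> pd.DataFrame:
    """Assemble a long-format results table from estimation outputs.

    Parameters
    ----------
    estimates:
        Pairs ``(contrast_name, result)``.  Allowed result types per
        layout: ``study1_peb1`` takes lists of coefficient estimates (LPM
        columns); ``study1_spillover`` takes spillover decompositions (one
        column per treatment contrast, with the bootstrapped CI of the
        indirect effect and the first-stage F); ``moderation`` takes
        moderated decompositions.
    layout:
        ``study1_peb1`` | ``study1_spillover`` | ``moderation``.

    The Benjamini-Hochberg adjustment is applied across all coefficient
    p-values of the table (one family per table).
    """
    if layout not in ("study1_peb1", "study1_spillover", "moderation"):
        raise ValueError(f"unknown layout {layout!r}")
    rows: list[tuple] = []
    for contrast, result in estimates:
        if layout == "study1_peb1":
            if not isinstance(result, (list, tuple)):
                raise ValueError(f"layout {layout}: expected coefficient list")
            rows.extend(_coefficient_rows(contrast, result))
        elif layout == "study1_spillover":
            if not isinstance(result, SpilloverDecomposition):
                raise ValueError(f"layout {layout}: expected SpilloverDecomposition")
            rows.extend(
                _coefficient_rows(
                    contrast, [result.beta_prime, result.delta_prime, result.tau]
                )
            )
            rows.append((contrast, "indirect", "estimate", result.indirect))
            rows.append((contrast, "indirect", "ci_low", result.indirect_ci95[0]))
            rows.append((contrast, "indirect", "ci_high", result.indirect_ci95[1]))
            rows.append((contrast, "stage1", "first_stage_F", result.first_stage_F))
            rows.append((contrast, "sample", "n", float(result.n)))
        else:
            if not isinstance(result, ModeratedDecomposition):
                raise ValueError(f"layout {layout}: expected ModeratedDecomposition")
            coefs = [result.beta1_prime, result.beta2_prime, result.delta1_prime]
            if result.delta2_prime is not None:
                coefs.append(result.delta2_prime)
            rows.extend(_coefficient_rows(contrast, coefs))
            for j, F in enumerate(result.first_stage_Fs, start=1):
                rows.append((contrast, f"stage1_eq{j}", "first_stage_F", float(F)))
    df = pd.DataFrame(rows, columns=["contrast", "term", "statistic", "value"])
    if df.empty:
        return df
    # table-wise BH family over the raw coefficient p-values
    mask = df["statistic"] == "p_raw"
    if mask.any():
        adjusted = bh_adjust(df.loc[mask, "value"].to_numpy())
        extra = df.loc[mask, ["contrast", "term"]].copy()
        extra["statistic"] = "p_bh"
        extra["value"] = adjusted
        df = pd.concat([df, extra], ignore_index=True)
    return df


def load_config(path: str | pathlib.Path, allowed: set[str] | None = None) -> dict:
    """Load a YAML/JSON run config; unknown keys are rejected when ``allowed`` given."""
    path = pathlib.Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    if allowed is not None:
        unknown = set(data) - allowed
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return data
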
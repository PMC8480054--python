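"""Table readers/writers and model serialization.

Intervention tables are matrices with ``n`` rows and ``1 + P`` columns —
column 1 the administered food quantity, columns 2..P+1 the biomarker
measurements.  Biomarker-only tables carry just the ``P`` biomarker columns.
Two dialects are supported: ``csv`` (comma-delimited) and ``txt``
(whitespace-delimited); an optional header row is auto-detected (a first row
with any non-numeric token is treated as a header).  Decimal separator is
the period; scientific notation is accepted.

Fitted models are serialized to a versioned NumPy ``.npz`` container
(chains stored bit-exactly, metadata as JSON), portable across sessions.
"""

from __future__ import annotations

import json
import zipfile
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .gating import GatingParameters
from .model_core import BiomarkerOnlyData, InterventionData
from .sampler import FittedModel, build_summary_table

__all__ = ["read_intervention_table", "read_biomarker_table", "write_table",
           "write_summary_table", "save_model", "load_model",
           "ModelFileError", "MODEL_FORMAT_VERSION"]

MODEL_FORMAT_VERSION = 1


class ModelFileError(RuntimeError):
    """Raised when a serialized model cannot be read back."""


def _detect_sep(path: Path, fmt: Optional[str]) -> str:
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower() or "csv"
    fmt = fmt.lower()
    if fmt == "csv":
        return ","
    if fmt == "txt":
        return r"\s+"
    raise ValueError(f"unsupported format {fmt!r}; use 'csv' or 'txt'")


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def _read_matrix(path, fmt: Optional[str]) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    sep = _detect_sep(path, fmt)
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise ValueError(f"{path}: file is empty")
    tokens = first.strip().split(",") if sep == "," else first.split()
    has_header = not all(_is_number(t.strip()) for t in tokens if t.strip() != "")
    df = pd.read_csv(path, sep=sep, header=0 if has_header else None,
                     skip_blank_lines=True)
    if df.shape[1] < 1:
        raise ValueError(f"{path}: no columns parsed")
    mat = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric value {df[col].iloc[i]!r} at data row "
                f"{i + 1}, column {j + 1}")
        if converted.isna().any():
            i = int(np.flatnonzero(converted.isna().to_numpy())[0])
            raise ValueError(f"{path}: missing value at data row {i + 1}, "
                             f"column {j + 1}")
        mat[:, j] = converted.to_numpy()
    return mat


def read_intervention_table(path, fmt: Optional[str] = None,
                            unit: str = "grams") -> InterventionData:
    """Parse an intervention table (dose column + P biomarker columns)."""
    mat = _read_matrix(path, fmt)
    if mat.shape[1] < 2:
        raise ValueError(
            f"{path}: an intervention table needs at least 2 columns "
            "(food quantity + one biomarker), found "
            f"{mat.shape[1]}")
    return InterventionData(quantities=mat[:, 0], biomarkers=mat[:, 1:],
                            unit=unit)


def read_biomarker_table(path, fmt: Optional[str] = None,
                         expected_P: Optional[int] = None) -> BiomarkerOnlyData:
    """Parse a biomarker-only table; optionally enforce the column count."""
    mat = _read_matrix(path, fmt)
    if expected_P is not None and mat.shape[1] != expected_P:
        raise ValueError(
            f"{path}: expected {expected_P} biomarker columns (the model's "
            f"P) but found {mat.shape[1]}")
    return BiomarkerOnlyData(biomarkers=mat)


def write_table(matrix: np.ndarray, path, fmt: Optional[str] = None,
                header: Optional[list] = None) -> None:
    """Write a numeric matrix in either dialect, losslessly (17 sig. digits)."""
    path = Path(path)
    sep = "," if _detect_sep(path, fmt) == "," else " "
    df = pd.DataFrame(np.asarray(matrix, dtype=float), columns=header)
    df.to_csv(path, sep=sep, index=False, header=header is not None,
              float_format="%.17g")


def write_summary_table(summaries: pd.DataFrame, path) -> None:
    """Write a posterior summary table as CSV with full printed precision."""
    summaries.to_csv(path, index=False, float_format="%.17g")


def save_model(model: FittedModel, path) -> None:
    """Serialize a fitted model to a versioned ``.npz`` container."""
    path = Path(path)
    payload = {f"chain_{k}": v for k, v in model.chains.items()}
    payload["format_version"] = np.array(MODEL_FORMAT_VERSION)
    payload["meta_json"] = np.array(json.dumps(model.meta))
    with open(path, "wb") as fh:
        np.savez(fh, **payload)


def load_model(path) -> FittedModel:
    """Load a serialized model; round-trips chains bit-exactly.

    Raises :class:`ModelFileError` on corrupt files or unknown format
    versions — never a silent misparse.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such model file: {path}")
    try:
        with np.load(path, allow_pickle=False) as archive:
            files = set(archive.files)
            if "format_version" not in files or "meta_json" not in files:
                raise ModelFileError(
                    f"{path}: not a recognized model container")
            version = int(archive["format_version"])
            if version > MODEL_FORMAT_VERSION:
                raise ModelFileError(
                    f"{path}: model format version {version} is newer than "
                    f"this package supports ({MODEL_FORMAT_VERSION})")
            meta = json.loads(str(archive["meta_json"]))
            chains = {k[len("chain_"):]: archive[k] for k in files
                      if k.startswith("chain_")}
    except (zipfile.BadZipFile, ValueError, KeyError, OSError, EOFError,
            json.JSONDecodeError) as exc:
        raise ModelFileError(f"{path}: corrupt or unreadable model file "
                             f"({exc})") from exc
    required = {"alpha", "beta", "sigma2", "theta2", "zeta", "w"}
    if not required <= set(chains):
        raise ModelFileError(f"{path}: model container is missing chains "
                             f"{sorted(required - set(chains))}")
    summaries = build_summary_table(chains, meta)
    S = chains["alpha"].shape[0]
    gating = GatingParameters(
        thresholds=chains["zeta"][S - 1],
        coefficients=chains["w"][S - 1],
        center=np.asarray(meta["gating_center"], dtype=float),
        scale=np.asarray(meta["gating_scale"], dtype=float),
        link=meta.get("gating_link", "cauchit"))
    return FittedModel(chains=chains, summaries=summaries, meta=meta,
                       gating_template=gating)
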
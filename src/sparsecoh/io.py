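"""Session, montage, feature-table and model I/O.

Sessions travel as delimited text (one column per electrode, header row
of electrode names, amplitudes in µV) or as EDF (read through mne; the
EDF physical-dimension fields are honored and converted to µV). A cohort
manifest is a delimited table linking each session file to participant,
arm, timepoint and symptom-change columns.

Models serialize as a plain-text key/value header plus a named weight
table, so a trained classifier — including its frozen standardization —
can be re-applied elsewhere without pickling.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import RawSession
from .svm import SparseHingeSVM


class IOError_(ValueError):
    """Schema or format problem in an input file."""


# ---------------------------------------------------------------------------
# sessions
# ---------------------------------------------------------------------------

def write_session_text(session: RawSession, path) -> Path:
    """One column per electrode, header row of electrode names, µV."""
    path = Path(path)
    df = pd.DataFrame(session.samples.T, columns=list(session.electrode_names))
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return path


def read_session_text(
    path,
    fs: float,
    electrode_names=None,
    arm: str = "active",
    timepoint: str = "pre",
    participant_id: str = "p0",
    symptoms: dict | None = None,
) -> RawSession:
    """Read a delimited-text session; columns are selected (and ordered)
    by ``electrode_names`` when given."""
    df = pd.read_csv(path, sep=None, engine="python")
    if electrode_names is not None:
        missing = [e for e in electrode_names if e not in df.columns]
        if missing:
            raise IOError_(
                f"{path}: missing electrode column(s): {', '.join(missing)}"
            )
        df = df[list(electrode_names)]
    return RawSession(
        samples=df.to_numpy(dtype=float).T,
        fs=fs,
        electrode_names=tuple(df.columns),
        arm=arm,
        timepoint=timepoint,
        participant_id=participant_id,
        symptoms=dict(symptoms or {}),
    )


def read_session_edf(
    path,
    electrode_names=None,
    arm: str = "active",
    timepoint: str = "pre",
    participant_id: str = "p0",
    symptoms: dict | None = None,
) -> RawSession:
    """Read an EDF session via mne; amplitudes converted to µV."""
    import mne  # deferred: EDF support is optional at runtime

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    picks = list(electrode_names) if electrode_names is not None else raw.ch_names
    missing = [c for c in picks if c not in raw.ch_names]
    if missing:
        raise IOError_(f"{path}: missing channel(s): {', '.join(missing)}")
    data = raw.get_data(picks=picks) * 1e6  # mne uses volts internally
    return RawSession(
        samples=data,
        fs=float(raw.info["sfreq"]),
        electrode_names=tuple(picks),
        arm=arm,
        timepoint=timepoint,
        participant_id=participant_id,
        symptoms=dict(symptoms or {}),
    )


def read_session(path, fs: float | None = None, **meta) -> RawSession:
    """Dispatch on extension: ``.edf`` via mne, anything else as text."""
    p = Path(path)
    if p.suffix.lower() == ".edf":
        return read_session_edf(p, **meta)
    if fs is None:
        raise IOError_("text sessions need an explicit sampling rate fs")
    return read_session_text(p, fs=fs, **meta)


# ---------------------------------------------------------------------------
# cohort manifest
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["participant", "arm", "timepoint", "file", "fs"]


def write_cohort(sessions, out_dir, fmt: str = "tsv") -> Path:
    """Write sessions plus a manifest table; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in sessions:
        fname = f"{s.participant_id}_{s.timepoint}.{fmt}"
        write_session_text(s, out_dir / fname)
        row = {
            "participant": s.participant_id,
            "arm": s.arm,
            "timepoint": s.timepoint,
            "file": fname,
            "fs": s.fs,
        }
        row.update(s.symptoms)
        rows.append(row)
    manifest = pd.DataFrame(rows)
    mpath = out_dir / "manifest.tsv"
    manifest.to_csv(mpath, sep="\t", index=False)
    return mpath


def read_cohort(manifest_path) -> list[RawSession]:
    """Load every session listed in a cohort manifest."""
    mpath = Path(manifest_path)
    df = pd.read_csv(mpath, sep="\t")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise IOError_(
            f"{mpath}: manifest missing column(s): {', '.join(missing)}"
        )
    symptom_cols = [c for c in df.columns if c.endswith("_pct_change")]
    sessions = []
    for _, row in df.iterrows():
        sessions.append(
            read_session(
                mpath.parent / row["file"],
                fs=float(row["fs"]),
                arm=row["arm"],
                timepoint=row["timepoint"],
                participant_id=str(row["participant"]),
                symptoms={
                    c: float(row[c]) for c in symptom_cols
                    if np.isfinite(row[c])
                },
            )
        )
    return sessions


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def features_to_frame(rows: list[dict]) -> pd.DataFrame:
    """Stack per-session feature dicts into the long-format cohort table."""
    return pd.DataFrame(rows)


def write_features(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_features(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

def save_model(model: SparseHingeSVM, path) -> Path:
    """Plain-text serialization: key/value header + named weight table."""
    path = Path(path)
    names = model.feature_names_ or tuple(
        f"f{j}" for j in range(model.n_features_in_)
    )
    lines = [
        "# sparsecoh linear model",
        f"C\t{float(model.C)!r}",
        f"standardize\t{int(model.standardize)}",
        f"fit_intercept\t{int(model.fit_intercept)}",
        f"intercept\t{float(model.intercept_)!r}",
        f"classes\t{model.classes_[0]}\t{model.classes_[1]}",
        "feature\tweight\tscale_mean\tscale_std",
    ]
    for j, name in enumerate(names):
        lines.append(
            f"{name}\t{float(model.coef_[j])!r}"
            f"\t{float(model.scale_mean_[j])!r}"
            f"\t{float(model.scale_std_[j])!r}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def load_model(path) -> SparseHingeSVM:
    lines = Path(path).read_text().strip().splitlines()
    header: dict[str, list[str]] = {}
    table_at = None
    for i, line in enumerate(lines):
        if line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0] == "feature":
            table_at = i + 1
            break
        header[parts[0]] = parts[1:]
    if table_at is None:
        raise IOError_(f"{path}: no weight table found")

    names, coefs, mus, sds = [], [], [], []
    for line in lines[table_at:]:
        name, w, mu, sd = line.split("\t")
        names.append(name)
        coefs.append(float(w))
        mus.append(float(mu))
        sds.append(float(sd))

    model = SparseHingeSVM(
        C=float(header["C"][0]),
        standardize=bool(int(header["standardize"][0])),
        fit_intercept=bool(int(header["fit_intercept"][0])),
    )
    model.coef_ = np.array(coefs)
    model.intercept_ = float(header["intercept"][0])
    model.scale_mean_ = np.array(mus)
    model.scale_std_ = np.array(sds)
    model.n_features_in_ = len(names)
    model.feature_names_ = tuple(names)
    cls = header["classes"]
    model.classes_ = np.array(
        [_maybe_number(cls[0]), _maybe_number(cls[1])]
    )
    return model


def _maybe_number(s: str):
    try:
        return float(s)
    except ValueError:
        return s


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def sha256_of(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_json_report(obj: dict, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path
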
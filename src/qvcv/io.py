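"""File formats and run configuration.

All tabular files are comma-separated UTF-8 text with '#'-prefixed
provenance header lines (package version, config hash, seed); models,
panels and configs are JSON.  Consonant and vowel labels use ASCII aliases
in files ('sh' for ʃ, 'a' for ɑ) and canonical IPA in memory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .core import (
    AIDED_CONDITIONS,
    CONSONANTS,
    OTHER,
    VOWELS,
    ConfusionMatrix,
    ListenerMeta,
    TrialRecord,
    ascii_label,
    canonical_label,
)

SESSION_COLUMNS = (
    "listener_id",
    "session_id",
    "block",
    "consonant",
    "vowel",
    "recording",
    "snr_db",
    "response",
    "aided",
    "correct",
)

META_COLUMNS = ("listener_id", "measured_pta_db_hl", "category", "test_ear")


class SessionFormatError(ValueError):
    """Malformed session file; message names the offending line."""


@dataclass
class RunConfig:
    """Analysis configuration with the packaged defaults."""

    panel_path: str | None = None
    lam: float = 3.0
    split_fraction: float = 0.7
    n_cv_repeats: int = 100
    pca_variance: float = 0.95
    excess_threshold_db: float = 5.0
    auc_threshold: float = 0.9
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must be in (0, 1)")
        if not 0.0 < self.pca_variance <= 1.0:
            raise ValueError("pca_variance must be in (0, 1]")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        obj = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(obj, dict):
            raise ValueError("config file must hold a mapping")
        if "lambda" in obj:
            obj["lam"] = obj.pop("lambda")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(obj) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**obj)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["lambda"] = d.pop("lam")
        return d

    @property
    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("output_dir", None)  # where results land is not analysis state
        blob = json.dumps(d, sort_keys=True, ensure_ascii=False)
        return hashlib.sha256(blob.encode("utf-8")).hexdigest()[:12]


def provenance_header(config: RunConfig | None = None, seed: int | None = None) -> str:
    from . import __version__

    parts = [f"# qvcv v{__version__}"]
    if config is not None:
        parts.append(f"config_hash={config.config_hash}")
    if seed is not None:
        parts.append(f"seed={seed}")
    return " ".join(parts)


def write_sessions(
    trials: Iterable[TrialRecord],
    path: str | Path,
    config: RunConfig | None = None,
    seed: int | None = None,
) -> None:
    """Write trial records as a comma-separated session file."""
    lines = [provenance_header(config, seed), ",".join(SESSION_COLUMNS)]
    for t in trials:
        lines.append(
            ",".join(
                [
                    t.listener_id,
                    t.session_id,
                    str(t.block),
                    ascii_label(t.consonant),
                    ascii_label(t.vowel),
                    str(t.recording),
                    format(t.snr_db, "g"),
                    ascii_label(t.response),
                    t.aided,
                    str(int(t.correct)),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_sessions(path: str | Path) -> list[TrialRecord]:
    """Read and validate a session file; errors carry 1-based line numbers."""
    text = Path(path).read_text(encoding="utf-8")
    trials: list[TrialRecord] = []
    header: list[str] | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = [f.strip() for f in line.split(",")]
        if header is None:
            header = fields
            missing = [c for c in SESSION_COLUMNS if c not in header and c != "correct"]
            if missing:
                raise SessionFormatError(
                    f"line {lineno}: missing columns {missing}"
                )
            continue
        if len(fields) != len(header):
            raise SessionFormatError(
                f"line {lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        row = dict(zip(header, fields))
        try:
            consonant = canonical_label(row["consonant"])
            vowel = canonical_label(row["vowel"])
            response = canonical_label(row["response"])
            if consonant not in CONSONANTS:
                raise ValueError(f"unknown consonant label {row['consonant']!r}")
            if vowel not in VOWELS:
                raise ValueError(f"unknown vowel label {row['vowel']!r}")
            if response != OTHER and response not in CONSONANTS:
                raise ValueError(f"unknown response label {row['response']!r}")
            snr = float(row["snr_db"])
            if not math.isfinite(snr):
                raise ValueError(f"non-finite snr_db {row['snr_db']!r}")
            trial = TrialRecord(
                listener_id=row["listener_id"],
                session_id=row["session_id"],
                block=int(row["block"]),
                consonant=consonant,
                vowel=vowel,
                recording=int(row["recording"]),
                snr_db=snr,
                response=response,
                aided=row.get("aided", "unaided"),
            )
            if "correct" in row and row["correct"] not in ("", None):
                stated = bool(int(row["correct"]))
                if stated != trial.correct:
                    raise ValueError(
                        "stated correctness disagrees with response == consonant"
                    )
        except (ValueError, KeyError) as exc:
            raise SessionFormatError(f"line {lineno}: {exc}") from exc
        trials.append(trial)
    if header is None:
        raise SessionFormatError("empty file: no header row")
    return trials


def write_listener_meta(
    metas: Iterable[ListenerMeta],
    path: str | Path,
    config: RunConfig | None = None,
    seed: int | None = None,
) -> None:
    lines = [provenance_header(config, seed), ",".join(META_COLUMNS)]
    for m in metas:
        lines.append(
            f"{m.listener_id},{format(m.measured_pta_db_hl, 'g')},{m.category},{m.test_ear}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_listener_meta(path: str | Path) -> list[ListenerMeta]:
    text = Path(path).read_text(encoding="utf-8")
    metas: list[ListenerMeta] = []
    header: list[str] | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = [f.strip() for f in line.split(",")]
        if header is None:
            header = fields
            continue
        row = dict(zip(header, fields))
        try:
            metas.append(
                ListenerMeta(
                    listener_id=row["listener_id"],
                    measured_pta_db_hl=float(row["measured_pta_db_hl"]),
                    category=row.get("category", ""),
                    test_ear=row.get("test_ear", "right"),
                )
            )
        except (ValueError, KeyError) as exc:
            raise SessionFormatError(f"line {lineno}: {exc}") from exc
    if header is None:
        raise SessionFormatError("empty file: no header row")
    return metas


def write_confusion_matrix(cm: ConfusionMatrix, path: str | Path) -> None:
    """Export a labeled confusion matrix as comma-separated text."""
    lines = [
        f"# qvcv confusion matrix listener={cm.listener_id} aided={cm.aided}",
        "presented," + ",".join(ascii_label(r) for r in cm.response_labels),
    ]
    for i, c in enumerate(cm.presented_labels):
        lines.append(ascii_label(c) + "," + ",".join(str(v) for v in cm.counts[i]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
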
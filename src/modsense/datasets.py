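"""Thin, optional adapters for real sound corpora.

The simulations and all tests run on synthetic corpora; these helpers only
map externally downloaded datasets onto the same manifest schema so training
and evaluation are corpus-agnostic.

* Everyday sounds: a 50-category, 5-fold corpus of 5 s clips at 44.1 kHz.
  Folds 1-3 become the parameter-update split, fold 4 early stopping, fold 5
  validation; trailing absolute-zero padding is trimmed.
* Speech: phone-labelled utterances whose 61 phone classes are folded to the
  conventional 39 (glottal stop ``q`` is dropped); the mapping ships as a
  fixture CSV.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .synthetic_data import Corpus

__all__ = [
    "trim_zero_tail",
    "esc50_corpus",
    "phone_fold_table",
    "fold_phone",
]


def trim_zero_tail(clip: np.ndarray) -> np.ndarray:
    """Drop the run of exact zeros padding the end of a clip, if any."""
    nz = np.flatnonzero(clip)
    return clip[: nz[-1] + 1] if nz.size else clip[:0]


def _read_wav(path) -> tuple[float, np.ndarray]:
    sr, data = wavfile.read(path)
    if np.issubdtype(data.dtype, np.integer):
        data = data / np.iinfo(data.dtype).max
    if data.ndim > 1:
        data = data.mean(axis=1)
    return float(sr), np.asarray(data, dtype=float)


def esc50_corpus(root, meta_csv: str = "meta/esc50.csv",
                 audio_dir: str = "audio") -> Corpus:
    """Load an ESC-50-layout directory into a :class:`Corpus`.

    Expects the stock metadata CSV (columns filename, fold, target).  Splits:
    folds 1-3 -> update, 4 -> early_stop, 5 -> validation.
    """
    root = Path(root)
    meta = pd.read_csv(root / meta_csv)
    clips, rows = [], []
    sr_seen = None
    for rec in meta.itertuples():
        sr, data = _read_wav(root / audio_dir / rec.filename)
        sr_seen = sr
        clips.append(trim_zero_tail(data))
        split = {1: "update", 2: "update", 3: "update",
                 4: "early_stop", 5: "validation"}[int(rec.fold)]
        rows.append({"clip_id": Path(rec.filename).stem,
                     "category": int(rec.target), "split": split,
                     "filename": rec.filename})
    return Corpus(clips=clips, manifest=pd.DataFrame(rows), sample_rate=sr_seen)


def phone_fold_table() -> dict[str, str]:
    """The 61-to-39 phone folding map; phones mapping to '' are discarded."""
    with resources.files("modsense.data").joinpath("timit_phone_fold.csv").open() as fh:
        table = pd.read_csv(fh, keep_default_na=False)
    return dict(zip(table["phone61"], table["phone39"]))


def fold_phone(phone: str, table: dict[str, str] | None = None) -> str | None:
    """Fold one phone label; returns None for labels that are discarded."""
    table = table or phone_fold_table()
    if phone not in table:
        raise KeyError(f"unknown phone label {phone!r}")
    return table[phone] or None
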
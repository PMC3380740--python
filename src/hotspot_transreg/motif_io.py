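"""Motif matrix readers (JASPAR, TRANSFAC, MEME minimal) and the hit-table TSV.

Format parsing is delegated to :mod:`Bio.motifs`; matrices come out as
:class:`~hotspot_transreg.motif_scan.MotifMatrix` rows in A,C,G,T order.
JASPAR and TRANSFAC matrices carry observation counts, MEME minimal-format
motifs carry probabilities; both are accepted since rows are normalized at
scoring time.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from .motif_scan import ALPHABET, MotifHit, MotifMatrix

_FORMATS = {
    ".jaspar": "jaspar",
    ".pfm": "jaspar",
    ".dat": "transfac",
    ".transfac": "transfac",
    ".meme": "minimal",
}

HIT_COLUMNS = ["motif", "region", "offset", "strand", "score", "p_value", "q_value"]


def _convert(m, fallback_name: str) -> MotifMatrix:
    name = m.name or None
    if not name and isinstance(m, dict):  # TRANSFAC records are dict-like
        name = m.get("NA") or m.get("ID")
    name = name or getattr(m, "matrix_id", None) or fallback_name
    counts = np.column_stack([np.asarray(m.counts[b], dtype=float) for b in ALPHABET])
    return MotifMatrix(str(name), counts)


def read_motifs(path: str | Path, fmt: str | None = None) -> list[MotifMatrix]:
    """Read all motifs in a file; format inferred from the extension if omitted.

    ``fmt`` is one of ``jaspar``, ``transfac``, ``minimal`` (MEME minimal
    motif format).
    """
    path = Path(path)
    if fmt is None:
        try:
            fmt = _FORMATS[path.suffix.lower()]
        except KeyError:
            raise ValueError(f"cannot infer motif format from {path.suffix!r}; pass fmt=")
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, fmt)
    out = [_convert(m, f"{path.stem}_{i}") for i, m in enumerate(parsed)]
    if not out:
        raise ValueError(f"no motifs parsed from {path}")
    return out


def read_jaspar(path: str | Path) -> list[MotifMatrix]:
    return read_motifs(path, "jaspar")


def read_transfac(path: str | Path) -> list[MotifMatrix]:
    return read_motifs(path, "transfac")


def read_meme(path: str | Path) -> list[MotifMatrix]:
    return read_motifs(path, "minimal")


def write_jaspar(mats: Sequence[MotifMatrix], path: str | Path) -> None:
    """Write matrices in JASPAR PFM text (one count row per base)."""
    with open(path, "w") as fh:
        for m in mats:
            fh.write(f">{m.name} {m.name}\n")
            for b, base in enumerate(ALPHABET):
                row = " ".join(f"{v:g}" for v in m.counts[:, b])
                fh.write(f"{base} [ {row} ]\n")


def hits_to_frame(hits: Iterable[MotifHit]) -> pd.DataFrame:
    rows = [
        (h.motif, h.region_id, h.offset, h.strand, h.score, h.p_value, h.q_value) for h in hits
    ]
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def write_hits_tsv(hits: Sequence[MotifHit], path: str | Path, header_comment: str = "") -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        hits_to_frame(hits).to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_hits_tsv(path: str | Path) -> list[MotifHit]:
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for row in df.itertuples(index=False):
        q = None if pd.isna(row.q_value) else float(row.q_value)
        out.append(
            MotifHit(
                str(row.motif), str(row.region), int(row.offset), str(row.strand),
                float(row.score), float(row.p_value), q,
            )
        )
    return out
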
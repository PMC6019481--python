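"""Plain-text table formats: spot/design/matrix TSVs and GMT gene sets.

All tables are tab-separated UTF-8 with a header row and "." decimals so
that every artifact is diff-able and language-neutral.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from protectomics.normalize import SPOT_COLUMNS, ExpressionMatrix
from protectomics.pathway import GeneSet

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: per line, set name, description, member symbols.

    Duplicate symbols within a set are deduplicated with a warning; empty
    sets and malformed lines are rejected with the line number.
    """
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: malformed GMT line "
                    "(need name, description and at least one symbol)"
                )
            name, desc, *symbols = parts
            symbols = [s for s in symbols if s]
            unique = list(dict.fromkeys(symbols))
            if len(unique) < len(symbols):
                log.warning("%s:%d: duplicate symbols in set %s deduplicated",
                            path, lineno, name)
            if not unique:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets.append(GeneSet(name, tuple(unique), desc))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *gs.members]) + "\n")


def read_spot_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "spot": str},
                     keep_default_na=False,
                     na_values={"fg": [""], "bg": [""]})
    missing = [c for c in SPOT_COLUMNS if c not in df.columns and c != "spot"]
    if missing:
        raise ValueError(f"{path}: spot table missing columns {missing}")
    df["control_flag"] = df["control_flag"].astype(str).str.lower().isin(
        ("true", "1", "yes"))
    df["fg"] = df["fg"].astype(float)
    df["bg"] = df["bg"].astype(float)
    return df


def write_spot_table(spots: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in SPOT_COLUMNS if c in spots.columns]
    spots[cols].to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_design_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = ["array_id", "channel", "condition", "replicate"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: design table missing columns {missing}")
    return df


def write_design_table(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t", index=False)


def _sample_label(condition: str, replicate: int) -> str:
    return f"{condition}_{replicate}"


def write_matrix(em: ExpressionMatrix, path: str | Path) -> None:
    """Genes x samples TSV with columns like ``CON_1``; masked entries
    are written empty."""
    out = em.values.where(em.mask)
    out.columns = [_sample_label(c, r) for c, r in em.values.columns]
    out.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_matrix(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a matrix TSV back into (values, mask) with the two-level
    (condition, replicate) column index."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    cols = pd.MultiIndex.from_tuples(
        [(c.rsplit("_", 1)[0], int(c.rsplit("_", 1)[1])) for c in df.columns],
        names=["condition", "replicate"],
    )
    df.columns = cols
    mask = df.notna()
    return df.fillna(0.0), mask


def write_condition_stats(em: ExpressionMatrix, path: str | Path) -> None:
    """Per-gene per-condition mean, pooled CV and valid-replicate count."""
    frames = []
    for cond in em.conditions:
        s = em.condition_stats(cond)
        s.insert(0, "condition", cond)
        frames.append(s.reset_index())
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def default_pathway_panel() -> Path:
    """Path of the packaged synthetic 12-pathway GMT panel."""
    return Path(__file__).parent / "data" / "pathways_synthetic.gmt"


def default_common_genes() -> Path:
    """Path of the packaged ESG/neurotransmission common-gene set."""
    return Path(__file__).parent / "data" / "common_genes.gmt"
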
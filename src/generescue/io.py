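"""TSV/GMT readers and writers with schema validation.

Everything on disk is tab-separated text. Readers validate eagerly and fail
with the offending row/column named; every writer produces files its paired
reader accepts (round-trip property).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from generescue.constants import GENOTYPES


def read_counts(path: str | Path) -> pd.DataFrame:
    """Gene-by-sample integer count matrix (first column: gene ids)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty count file") from None
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns found")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][:3].tolist()
        raise ValueError(f"{path}: duplicate gene ids, e.g. {dup}")
    if pd.Index(df.columns).has_duplicates:
        raise ValueError(f"{path}: duplicate sample ids")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals != vals.round())
        if bad.any():
            gene = df.index[bad.to_numpy().argmax()]
            raise ValueError(
                f"{path}: non-integer or negative count at gene {gene!r}, "
                f"sample {col!r}"
            )
    out = df.astype("int64")
    out.index.name = "gene"
    return out


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_samples(path: str | Path) -> pd.DataFrame:
    """Sample table: sample, genotype, sex, litter (litter may be empty)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    for col in ("genotype", "sex"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if "litter" not in df.columns:
        df["litter"] = ""
    unknown = set(df["genotype"]) - set(GENOTYPES)
    if unknown:
        raise ValueError(
            f"{path}: unknown genotype label(s) {sorted(unknown)}; "
            f"allowed: {list(GENOTYPES)}"
        )
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate sample ids")
    if "size_factor" in df.columns:
        df["size_factor"] = df["size_factor"].astype(float)
    df.index.name = "sample"
    return df


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index_label="sample")


def read_weights(path: str | Path) -> pd.DataFrame:
    """Embryo weights: embryo, litter, genotype, weight_g (grams, > 0)."""
    df = pd.read_csv(path, sep="\t", dtype={"embryo": str, "litter": str,
                                            "genotype": str})
    required = {"embryo", "litter", "genotype", "weight_g"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    unknown = set(df["genotype"]) - set(GENOTYPES)
    if unknown:
        raise ValueError(
            f"{path}: unknown genotype label(s) {sorted(unknown)}; "
            f"allowed: {list(GENOTYPES)}"
        )
    df["weight_g"] = pd.to_numeric(df["weight_g"])
    if (df["weight_g"] <= 0).any():
        row = df.index[df["weight_g"] <= 0][0]
        raise ValueError(f"{path}: non-positive weight at row {row + 2} "
                         f"(embryo {df.at[row, 'embryo']!r})")
    return df


def write_weights(weights: pd.DataFrame, path: str | Path) -> None:
    weights.to_csv(path, sep="\t", index=False)


def read_cross(path: str | Path) -> pd.DataFrame:
    """Cross outcome: category, observed; optional expected column(s)."""
    df = pd.read_csv(path, sep="\t", dtype={"category": str})
    if "category" not in df.columns or "observed" not in df.columns:
        raise ValueError(f"{path}: need 'category' and 'observed' columns")
    df["observed"] = pd.to_numeric(df["observed"])
    if (df["observed"] < 0).any() or (df["observed"] % 1 != 0).any():
        raise ValueError(f"{path}: observed counts must be non-negative integers")
    for col in df.columns:
        if col.startswith("expected"):
            df[col] = pd.to_numeric(df[col])
            if (df[col] < 0).any():
                raise ValueError(f"{path}: negative expected counts in {col!r}")
    return df


def write_cross(cross: pd.DataFrame, path: str | Path) -> None:
    cross.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT gene sets: tab-separated name, description, gene ids."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT lines need >= 3 tab-separated "
                    f"fields (name, description, genes), got {len(fields)}"
                )
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set {name!r}")
            sets[name] = [g for g in fields[2:] if g]
    return sets


def write_gmt(gene_sets: Mapping[str, Sequence[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            desc = (descriptions or {}).get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_config(path: str | Path) -> dict:
    """Plain-text key-value run configuration (YAML subset)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a key-value mapping")
    return cfg


def write_config(config: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(config), fh, sort_keys=True)
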
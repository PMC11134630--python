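"""Readers and writers for the pipeline's plain-text formats.

Everything is TSV (pandas) or GMT-like gene-set files; the writers emit
exactly what the corresponding readers consume, so simulated data can be
round-tripped through disk like real data would be.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .chc import CompositionProfile
from .enrichment import GeneSet
from .expression import CountMatrix
from .mating import ChasingRecord, MatingCountTable


# -- chasing records ----------------------------------------------------

def read_chasing(path: str | Path) -> list[ChasingRecord]:
    df = pd.read_csv(path, sep="\t")
    _require(df, ["trial_id", "setup", "chasing_time"], path)
    return [ChasingRecord(str(r.trial_id), str(r.setup), float(r.chasing_time))
            for r in df.itertuples()]


def write_chasing(records: list[ChasingRecord], path: str | Path) -> None:
    pd.DataFrame([vars(r) for r in records]).to_csv(path, sep="\t", index=False)


# -- mating-pair counts -------------------------------------------------

def read_mating_table(path: str | Path) -> MatingCountTable:
    df = pd.read_csv(path, sep="\t")
    _require(df, ["female_pop", "male_pop", "count"], path)
    pops = sorted(set(df["female_pop"]) | set(df["male_pop"]))
    if len(pops) != 2:
        raise ValueError(f"{path}: expected exactly 2 populations, got {pops}")
    counts = np.zeros((2, 2), dtype=int)
    for r in df.itertuples():
        counts[pops.index(r.female_pop), pops.index(r.male_pop)] += int(r.count)
    return MatingCountTable(pops=(pops[0], pops[1]), counts=counts)


def write_mating_table(t: MatingCountTable, path: str | Path) -> None:
    rows = [{"female_pop": t.pops[i], "male_pop": t.pops[j],
             "count": int(t.counts[i, j])}
            for i in range(2) for j in range(2)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -- CHC composition profiles -------------------------------------------

def read_compositions(path: str | Path) -> list[CompositionProfile]:
    df = pd.read_csv(path, sep="\t")
    meta = ["sample_id", "sex", "group", "replicate"]
    _require(df, meta, path)
    compounds = [c for c in df.columns if c not in meta]
    return [CompositionProfile(str(r["sample_id"]), str(r["sex"]),
                               str(r["group"]), str(r["replicate"]),
                               r[compounds].to_numpy(dtype=float))
            for _, r in df.iterrows()]


def write_compositions(profiles: list[CompositionProfile], path: str | Path,
                       compound_names: list[str] | None = None) -> None:
    k = len(profiles[0].abundances)
    names = compound_names or [f"c{i+1}" for i in range(k)]
    rows = []
    for p in profiles:
        row = {"sample_id": p.sample_id, "sex": p.sex, "group": p.group,
               "replicate": p.replicate}
        row.update(dict(zip(names, p.abundances)))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -- diallel sheets ------------------------------------------------------

def read_diallel(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require(df, ["sire_pop", "dam_pop", "vial_id", "progeny_count"], path)
    return df


def write_diallel(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


# -- count matrices ------------------------------------------------------

def read_counts(counts_path: str | Path, meta_path: str | Path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    _require(meta.reset_index(), ["replicate", "group"], meta_path)
    if "library_size" in meta.columns:
        lib = meta["library_size"].astype(float)
    else:
        lib = counts.sum(axis=0).astype(float)
    meta = meta.loc[counts.columns]
    return CountMatrix(counts=counts, library_sizes=lib.loc[counts.columns],
                       sample_meta=meta[["replicate", "group"]])


def write_counts(m: CountMatrix, counts_path: str | Path,
                 meta_path: str | Path) -> None:
    m.counts.to_csv(counts_path, sep="\t")
    meta = m.sample_meta.copy()
    meta["library_size"] = m.library_sizes
    meta.to_csv(meta_path, sep="\t", index_label="sample_id")


# -- gene sets (GMT-like: name <tab> description <tab> genes...) ---------

def read_gmt(path: str | Path) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{i}: GMT line needs name, "
                                 "description and >= 1 gene")
            sets.append(GeneSet.of(parts[0], parts[2:]))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, "na", *sorted(s.genes)]) + "\n")


# -- tissue expression ---------------------------------------------------

def read_tissue_expr(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def _require(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
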
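"""Data model and I/O: the stem map, the five-matrix bundle, the natural-log
transform rule, and readers/writers for all tables.

File conventions: stem maps are tab-separated (tag, species, x, y); trait
and environment tables are CSV with a header and a label column;
phylogenies and dendrograms are Newick; every result writer emits CSV plus
a JSON run-metadata sidecar.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .errors import AlignmentError, ParseError, ValidationError

logger = logging.getLogger(__name__)

STEM_COLUMNS = ["tag", "species", "x", "y"]


@dataclass
class StemMap:
    """Tagged, mapped individuals in a rectangular plot.

    Coordinates are 0-based metres with the half-open convention
    0 <= x < plot_width, 0 <= y < plot_height, so every stem belongs to
    exactly one quadrat at every scale.
    """

    data: pd.DataFrame  # columns tag, species, x, y
    plot_width: float
    plot_height: float

    def __post_init__(self):
        missing = [c for c in STEM_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"stem map missing columns {missing}")
        df = self.data
        if (df["species"].astype(str).str.len() == 0).any():
            raise ValidationError("empty species labels in stem map")
        oob = ~(
            (df["x"] >= 0)
            & (df["x"] < self.plot_width)
            & (df["y"] >= 0)
            & (df["y"] < self.plot_height)
        )
        if oob.any():
            lines = (np.flatnonzero(oob.values) + 2)[:10]  # +2: header + 1-based
            raise ValidationError(
                f"{int(oob.sum())} stem(s) outside [0,{self.plot_width})x"
                f"[0,{self.plot_height}); first offending line(s): {lines.tolist()}"
            )
        dup = df["tag"].duplicated()
        if dup.any():
            logger.warning(
                "stem map has %d duplicated tag(s); keeping all rows", int(dup.sum())
            )

    @property
    def n_stems(self) -> int:
        return len(self.data)

    @property
    def species(self) -> list[str]:
        return sorted(self.data["species"].unique())


def read_stem_map(path, plot_width: float, plot_height: float) -> StemMap:
    """Read a tab-separated stem map (header: tag, species, x, y)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"cannot parse stem map {path}: {exc}") from exc
    missing = [c for c in STEM_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: header missing columns {missing}")
    for col in ("x", "y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            line = int(np.flatnonzero(bad.values)[0]) + 2
            raise ParseError(f"{path}: non-numeric {col!r} at line {line}")
        if vals.isna().any():
            line = int(np.flatnonzero(vals.isna().values)[0]) + 2
            raise ParseError(f"{path}: missing {col!r} at line {line}")
        df[col] = vals
    df["species"] = df["species"].astype(str)
    df["tag"] = df["tag"].astype(str)
    return StemMap(data=df[STEM_COLUMNS], plot_width=plot_width, plot_height=plot_height)


def write_stem_map(stem_map: StemMap, path) -> None:
    stem_map.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# log transform
# ---------------------------------------------------------------------------

def natural_log_transform(table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Natural-log transform of every column, made total.

    Strictly positive columns use log(x); columns with zeros or negatives
    in (-1, 0] use log1p; columns reaching -1 or below are shifted to
    log(x - min + 1).  The rule applied per column is returned and logged.
    """
    out = {}
    applied = {}
    for col in table.columns:
        x = table[col].astype(float)
        mn = x.min(skipna=True)
        if mn > 0:
            out[col] = np.log(x)
            applied[col] = "log"
        elif mn > -1:
            out[col] = np.log1p(x)
            applied[col] = "log1p"
        else:
            out[col] = np.log(x - mn + 1.0)
            applied[col] = f"log(x - {mn:.6g} + 1)"
    shifted = [c for c, rule in applied.items() if rule != "log"]
    if shifted:
        logger.info("log transform shifted non-positive columns: %s", shifted)
    return pd.DataFrame(out, index=table.index), applied


# ---------------------------------------------------------------------------
# five-matrix bundle
# ---------------------------------------------------------------------------

@dataclass
class FiveMatrixBundle:
    """Aligned matrices of the extended RLQ analysis.

    L: sites x species abundances; E: sites x environment; S: sites x
    spatial basis; T, P: species x species trait / phylogenetic distances.
    Row labels of L, E, S coincide; column labels of L coincide with the
    ids of T and P.
    """

    L: pd.DataFrame
    E: pd.DataFrame
    S: pd.DataFrame
    T: DistanceMatrix
    P: DistanceMatrix

    @property
    def site_ids(self) -> list[str]:
        return list(self.L.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.L.columns)


def _check_distance(name: str, M) -> DistanceMatrix:
    if isinstance(M, DistanceMatrix):
        return M
    if isinstance(M, pd.DataFrame):
        arr = M.values.astype(float)
        if not np.allclose(arr, arr.T, atol=1e-12):
            raise ValidationError(f"{name} is not symmetric")
        try:
            return DistanceMatrix(arr, ids=[str(i) for i in M.index])
        except Exception as exc:
            raise ValidationError(f"{name}: {exc}") from exc
    raise ValidationError(f"{name} must be a DistanceMatrix or labelled DataFrame")


def align_bundle(L, E, S, T, P) -> FiveMatrixBundle:
    """Restrict all five matrices to the intersection of their labels,
    ordered as in L, dropping species absent from every site and sites
    holding no stems."""
    T = _check_distance("T", T)
    P = _check_distance("P", P)
    sites = [s for s in L.index if s in set(E.index) & set(S.index)]
    species = [
        sp for sp in L.columns if sp in set(T.ids) & set(P.ids)
    ]
    if not sites:
        raise AlignmentError("no common site labels between L, E and S")
    if not species:
        raise AlignmentError("no common species labels between L, T and P")
    Lx = L.loc[sites, species].astype(float)
    # drop empty rows/columns after restriction
    keep_sp = Lx.sum(axis=0) > 0
    keep_si = Lx.sum(axis=1) > 0
    dropped_sp = int((~keep_sp).sum())
    dropped_si = int((~keep_si).sum())
    if dropped_sp or dropped_si:
        logger.info(
            "alignment dropped %d empty species and %d empty sites",
            dropped_sp, dropped_si,
        )
    Lx = Lx.loc[keep_si, keep_sp]
    sites = list(Lx.index)
    species = list(Lx.columns)
    if not sites or not species:
        raise AlignmentError("no non-empty sites/species remain after alignment")
    return FiveMatrixBundle(
        L=Lx,
        E=E.loc[sites].astype(float),
        S=S.loc[sites].astype(float),
        T=T.filter(species),
        P=P.filter(species),
    )


# ---------------------------------------------------------------------------
# table / tree round-trips
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path, metadata: dict | None = None,
                index_label: str = "id") -> None:
    """CSV writer with full float precision plus a JSON metadata sidecar."""
    path = Path(path)
    df.to_csv(path, index_label=index_label, float_format="%.17g")
    if metadata is not None:
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps(metadata, indent=2, sort_keys=True))


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_distance_matrix(D: DistanceMatrix, path) -> None:
    pd.DataFrame(D.data, index=D.ids, columns=D.ids).to_csv(
        path, float_format="%.17g"
    )


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    return DistanceMatrix(df.values, ids=[str(i) for i in df.index])


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)
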
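"""Data containers and file I/O for spot-level spatial transcriptomics.

The central container is :class:`SpotSample`: a spots x genes count matrix,
its normalized/log-transformed counterpart, and planar spot coordinates.
Ligand-receptor candidates are held in :class:`LRDatabase`, a list of
:class:`LRPair` records that may carry multi-subunit ligands or receptors
(CellChatDB-style, subunits joined by ``_`` or ``&`` in the CSV).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread

logger = logging.getLogger(__name__)

SUBUNIT_DELIMS = ("_", "&")

#: accepted spellings for the three signalling classes
_SIGNALLING_SYNONYMS = {
    "secreted": "secreted",
    "secreted signaling": "secreted",
    "secreted signalling": "secreted",
    "ecm": "ecm",
    "ecm-receptor": "ecm",
    "contact": "contact",
    "cell-cell contact": "contact",
}


@dataclass
class SpotSample:
    """One slide: raw counts, optional normalized expression, coordinates.

    Attributes
    ----------
    spot_ids
        Unique spot barcodes, one per row of ``raw_counts``.
    gene_names
        Unique uppercased gene symbols (uppercasing makes database matching
        case-insensitive), one per column.
    raw_counts
        Non-negative spots x genes matrix.
    coords
        spots x 2 planar coordinates in platform units.
    expr
        Normalized, log-transformed spots x genes matrix; ``None`` until
        :func:`normalize_log` is applied.
    """

    spot_ids: pd.Index
    gene_names: pd.Index
    raw_counts: np.ndarray
    coords: np.ndarray
    expr: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.spot_ids = pd.Index(self.spot_ids).astype(str)
        self.gene_names = pd.Index(self.gene_names).astype(str)
        self.raw_counts = np.asarray(self.raw_counts, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        n, g = self.raw_counts.shape
        if len(self.spot_ids) != n:
            raise ValueError(
                f"{len(self.spot_ids)} spot ids but counts have {n} rows"
            )
        if len(self.gene_names) != g:
            raise ValueError(
                f"{len(self.gene_names)} gene names but counts have {g} columns"
            )
        if self.coords.shape != (n, 2):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{n} spots x 2 dimensions"
            )
        if np.isnan(self.coords).any():
            raise ValueError("coords contain NaN")
        if (self.raw_counts < 0).any():
            raise ValueError("raw_counts contain negative values")
        if not self.spot_ids.is_unique:
            raise ValueError("spot ids are not unique")
        if not self.gene_names.str.upper().is_unique:
            raise ValueError("gene names are not unique after uppercasing")
        if self.expr is not None:
            self.expr = np.asarray(self.expr, dtype=float)
            if self.expr.shape != self.raw_counts.shape:
                raise ValueError("expr shape does not match raw_counts")
            if not np.isfinite(self.expr).all():
                raise ValueError("expr contains non-finite values")

    @property
    def n_spots(self) -> int:
        return self.raw_counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.raw_counts.shape[1]

    def gene_index(self, gene: str) -> int:
        loc = self.gene_names.get_indexer([gene.upper()])[0]
        if loc < 0:
            raise KeyError(f"gene {gene!r} not found in sample")
        return int(loc)

    def expr_vector(self, gene: str) -> np.ndarray:
        """Normalized expression of one gene across spots."""
        if self.expr is None:
            raise ValueError("expr is empty; call normalize_log first")
        return self.expr[:, self.gene_index(gene)]

    @classmethod
    def from_expr(
        cls,
        expr: np.ndarray,
        coords: np.ndarray,
        gene_names,
        spot_ids=None,
    ) -> "SpotSample":
        """Build a sample directly from an expression matrix.

        Useful for feeding externally processed (or latent, simulated)
        expression into the statistics; ``raw_counts`` is filled with a
        non-negative shifted copy purely to satisfy the container contract.
        """
        expr = np.asarray(expr, dtype=float)
        if spot_ids is None:
            spot_ids = [f"spot{i}" for i in range(expr.shape[0])]
        raw = expr - min(0.0, expr.min())
        return cls(
            spot_ids=pd.Index(spot_ids),
            gene_names=pd.Index([g.upper() for g in gene_names]),
            raw_counts=raw,
            coords=coords,
            expr=expr,
        )


def _read_table(path: Path) -> pd.DataFrame:
    sep = "\t" if Path(path).suffix.lower() in {".tsv", ".txt"} else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def _dedup_genes(counts: pd.DataFrame) -> pd.DataFrame:
    counts.columns = counts.columns.str.upper()
    if not counts.columns.is_unique:
        ndup = counts.columns.duplicated().sum()
        logger.warning("summing counts over %d duplicate gene symbols", ndup)
        counts = counts.T.groupby(level=0, sort=False).sum().T
    return counts


def _find_sidecar(mtx_path: Path, stems: tuple[str, ...]) -> Path:
    """Locate a 10x-style sidecar (barcodes/features) next to an .mtx file."""
    folder = mtx_path.parent
    for stem in stems:
        for suffix in (".tsv", ".txt", ".csv"):
            cand = folder / f"{stem}{suffix}"
            if cand.exists():
                return cand
    raise FileNotFoundError(
        f"no sidecar file matching {stems} found next to {mtx_path}"
    )


def read_sample(counts_path, coords_path, format: str | None = None) -> SpotSample:
    """Read counts + coordinates into a :class:`SpotSample`.

    Parameters
    ----------
    counts_path
        Dense CSV/TSV (spots x genes, first column = spot id) or a
        MatrixMarket ``.mtx`` file in 10x layout (genes x spots, with
        ``barcodes.tsv`` and ``features.tsv``/``genes.tsv`` alongside).
    coords_path
        CSV/TSV with spot id in the first column then x, y.
    format
        ``"csv"`` or ``"mtx"``; inferred from the extension when ``None``.

    Counts and coordinates are matched by spot barcode when the barcode sets
    agree; a mismatch in spot number is fatal and reports both shapes.
    """
    counts_path, coords_path = Path(counts_path), Path(coords_path)
    if format is None:
        format = "mtx" if counts_path.suffix.lower() == ".mtx" else "csv"

    if format == "mtx":
        mat = np.asarray(mmread(counts_path).todense(), dtype=float)
        barcodes = pd.read_csv(
            _find_sidecar(counts_path, ("barcodes",)), sep="\t", header=None
        )[0].astype(str)
        feat = pd.read_csv(
            _find_sidecar(counts_path, ("features", "genes")), sep="\t", header=None
        )
        # 10x features.tsv may carry (id, symbol, type); use the symbol column
        genes = feat[1] if feat.shape[1] > 1 else feat[0]
        if mat.shape == (len(genes), len(barcodes)):
            mat = mat.T  # genes x spots -> spots x genes
        elif mat.shape != (len(barcodes), len(genes)):
            raise ValueError(
                f"matrix shape {mat.shape} matches neither "
                f"(genes={len(genes)}, spots={len(barcodes)}) orientation"
            )
        counts = pd.DataFrame(mat, index=barcodes.values, columns=genes.values)
    elif format == "csv":
        counts = _read_table(counts_path)
    else:
        raise ValueError(f"unknown format {format!r}")

    counts = _dedup_genes(counts)
    coords = _read_table(coords_path)
    if coords.shape[1] < 2:
        raise ValueError("coords file needs at least two coordinate columns")
    coords = coords.iloc[:, :2]

    if coords.shape[0] != counts.shape[0]:
        raise ValueError(
            f"counts have {counts.shape[0]} spots but coords have "
            f"{coords.shape[0]} rows (counts shape {counts.shape}, "
            f"coords shape {coords.shape})"
        )
    counts_ids = pd.Index(counts.index.astype(str))
    coords_ids = pd.Index(coords.index.astype(str))
    if set(counts_ids) == set(coords_ids):
        coords = coords.loc[counts_ids]
    else:
        logger.warning("spot barcodes differ between files; matching by order")

    return SpotSample(
        spot_ids=counts_ids,
        gene_names=counts.columns,
        raw_counts=counts.to_numpy(dtype=float),
        coords=coords.to_numpy(dtype=float),
    )


def write_counts_csv(sample: SpotSample, path) -> None:
    """Write raw counts as a dense CSV (spots x genes, round-trippable)."""
    pd.DataFrame(
        sample.raw_counts, index=sample.spot_ids, columns=sample.gene_names
    ).to_csv(path)


def write_coords_csv(sample: SpotSample, path) -> None:
    pd.DataFrame(
        sample.coords, index=sample.spot_ids, columns=["x", "y"]
    ).to_csv(path)


def normalize_log(sample: SpotSample, scale: float = 1e4) -> SpotSample:
    """Library-size normalization to a fixed total, then log1p.

    ``expr = log(1 + scale * count / spot_total)`` per spot. Spots with zero
    total counts get all-zero expression rows (with a warning).
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    totals = sample.raw_counts.sum(axis=1)
    empty = totals == 0
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} spots have zero total counts; "
            "their expression is set to zero"
        )
    safe = np.where(empty, 1.0, totals)
    expr = np.log1p(scale * sample.raw_counts / safe[:, None])
    expr[empty] = 0.0
    return replace(sample, expr=expr)


# ---------------------------------------------------------------------------
# ligand-receptor database
# ---------------------------------------------------------------------------


@dataclass
class LRPair:
    """One candidate interaction: possibly multi-subunit on either side."""

    pair_id: str
    ligand_subunits: list[str]
    receptor_subunits: list[str]
    pathway: str = ""
    signalling_type: str = "secreted"

    def __post_init__(self) -> None:
        self.ligand_subunits = [s.upper() for s in self.ligand_subunits]
        self.receptor_subunits = [s.upper() for s in self.receptor_subunits]
        if not self.ligand_subunits or not self.receptor_subunits:
            raise ValueError(f"pair {self.pair_id}: empty subunit list")

    @property
    def ligand(self) -> str:
        return "_".join(self.ligand_subunits)

    @property
    def receptor(self) -> str:
        return "_".join(self.receptor_subunits)

    @property
    def key(self) -> tuple[tuple[str, ...], tuple[str, ...]]:
        return tuple(self.ligand_subunits), tuple(self.receptor_subunits)


@dataclass
class LRDatabase:
    pairs: list[LRPair] = field(default_factory=list)
    species: str = "human"
    version_tag: str = ""

    def __post_init__(self) -> None:
        ids = [p.pair_id for p in self.pairs]
        if len(set(ids)) != len(ids):
            raise ValueError("pair_id values are not unique within the database")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def get(self, pair_id: str) -> LRPair:
        for p in self.pairs:
            if p.pair_id == pair_id:
                return p
        raise KeyError(pair_id)

    @property
    def pair_ids(self) -> list[str]:
        return [p.pair_id for p in self.pairs]

    def subset(self, pair_ids) -> "LRDatabase":
        wanted = set(pair_ids)
        return LRDatabase(
            pairs=[p for p in self.pairs if p.pair_id in wanted],
            species=self.species,
            version_tag=self.version_tag,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pair_id": [p.pair_id for p in self.pairs],
                "ligand": [p.ligand for p in self.pairs],
                "receptor": [p.receptor for p in self.pairs],
                "pathway": [p.pathway for p in self.pairs],
                "signalling_type": [p.signalling_type for p in self.pairs],
            }
        )


def _split_subunits(symbol: str) -> list[str]:
    s = str(symbol).strip()
    for delim in SUBUNIT_DELIMS[1:]:
        s = s.replace(delim, SUBUNIT_DELIMS[0])
    return [part.strip().upper() for part in s.split(SUBUNIT_DELIMS[0]) if part.strip()]


def _normalize_signalling(value) -> str:
    key = str(value).strip().lower()
    if key in _SIGNALLING_SYNONYMS:
        return _SIGNALLING_SYNONYMS[key]
    logger.warning("unknown signalling type %r, treating as 'secreted'", value)
    return "secreted"


def read_lr_database(path, species: str = "human", version_tag: str = "") -> LRDatabase:
    """Parse a ligand-receptor database CSV.

    Required columns: ``ligand``, ``receptor``, ``pathway``,
    ``signalling_type``. ``pair_id`` is optional (synthesised as
    ``ligand_receptor`` when absent). Subunits are delimited by ``_`` or
    ``&``; gene symbols are uppercased.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("ligand", "receptor", "pathway", "signalling_type"):
        if col not in df.columns:
            raise ValueError(f"LR database is missing required column {col!r}")
    pairs: list[LRPair] = []
    seen_ids: set[str] = set()
    for _, row in df.iterrows():
        lig = _split_subunits(row["ligand"])
        rec = _split_subunits(row["receptor"])
        if not lig or not rec:
            logger.warning("skipping pair with empty subunit list: %s", dict(row))
            continue
        pid = row["pair_id"] if "pair_id" in df.columns else np.nan
        if pd.isna(pid) or not str(pid).strip():
            pid = "_".join(lig) + "_" + "_".join(rec)
        pid = str(pid).strip()
        if pid in seen_ids:
            logger.warning("skipping duplicate pair_id %r", pid)
            continue
        seen_ids.add(pid)
        pairs.append(
            LRPair(
                pair_id=pid,
                ligand_subunits=lig,
                receptor_subunits=rec,
                pathway=str(row["pathway"]),
                signalling_type=_normalize_signalling(row["signalling_type"]),
            )
        )
    return LRDatabase(pairs=pairs, species=species, version_tag=version_tag)


def write_lr_database(db: LRDatabase, path) -> None:
    db.to_dataframe().to_csv(path, index=False)


def filter_database(db: LRDatabase, sample: SpotSample, strict: bool = True) -> LRDatabase:
    """Restrict a database to pairs whose genes are measured in the sample.

    strict=True drops any pair with a missing subunit; strict=False keeps the
    pair using only the subunits present (at least one per side).
    """
    genes = set(sample.gene_names.str.upper())
    kept: list[LRPair] = []
    for p in db.pairs:
        lig = [s for s in p.ligand_subunits if s in genes]
        rec = [s for s in p.receptor_subunits if s in genes]
        if strict:
            if len(lig) == len(p.ligand_subunits) and len(rec) == len(p.receptor_subunits):
                kept.append(p)
        elif lig and rec:
            kept.append(
                LRPair(p.pair_id, lig, rec, p.pathway, p.signalling_type)
            )
    return LRDatabase(pairs=kept, species=db.species, version_tag=db.version_tag)


def shuffle_database(db: LRDatabase, n_pairs: int, seed: int) -> LRDatabase:
    """Negative-control database: re-pair ligands with non-partner receptors.

    No output pair reproduces a documented (ligand, receptor) combination,
    output pairs are distinct, and the result is reproducible under ``seed``.
    """
    if len(db) < 2:
        raise ValueError("need at least 2 documented pairs to shuffle")
    rng = np.random.default_rng(seed)
    documented = {p.key for p in db.pairs}

    ligands: list[tuple[str, ...]] = []
    lig_types: dict[tuple[str, ...], str] = {}
    receptors: list[tuple[str, ...]] = []
    for p in db.pairs:
        lkey, rkey = tuple(p.ligand_subunits), tuple(p.receptor_subunits)
        if lkey not in lig_types:
            ligands.append(lkey)
            lig_types[lkey] = p.signalling_type
        if rkey not in receptors:
            receptors.append(rkey)

    candidates = [
        (l, r)
        for l, r in itertools.product(ligands, receptors)
        if (l, r) not in documented
    ]
    if n_pairs > len(candidates):
        raise ValueError(
            f"requested {n_pairs} shuffled pairs but only {len(candidates)} "
            "non-documented combinations exist"
        )
    chosen = [candidates[i] for i in rng.choice(len(candidates), n_pairs, replace=False)]
    pairs = [
        LRPair(
            pair_id="_".join(l) + "_" + "_".join(r),
            ligand_subunits=list(l),
            receptor_subunits=list(r),
            pathway="shuffled_control",
            signalling_type=lig_types[l],
        )
        for l, r in chosen
    ]
    return LRDatabase(pairs=pairs, species=db.species, version_tag=db.version_tag + "+shuffled")
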
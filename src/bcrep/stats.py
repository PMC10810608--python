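"""Repertoire skew statistics over annotated rearrangement tables.

All operations consume the AIRR-style table produced by
:mod:`bcrep.annotate` (pandas DataFrame). Frequency denominators follow
repertoire-analysis convention: isotype and lambda-family shares are per
cell (cells with a productive light chain), gene-usage shares are per
productive record within the respective locus, and productivity fractions
are per raw read before any filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .germline import GermlineSet, Locus, SegmentClass, cassette_of
from .simulate import FAILURE_NON_IG

CHAIN_OF_LOCUS = {"IGH": "heavy", "IGK": "kappa", "IGL": "lambda"}


class EmptyTableError(ValueError):
    """Requested statistic over zero records."""


@dataclass
class UsageTable:
    """Relative frequencies over one categorical axis of a repertoire."""

    axis: str                      # isotype | lambda_family | v_gene | j_gene | vj_pair
    locus: str | None
    labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        if self.total == 0:
            return np.zeros(len(self.labels))
        return self.counts / self.total

    @property
    def empty(self) -> bool:
        return self.total == 0

    def __getitem__(self, label: str) -> float:
        return float(self.frequencies[self.labels.index(label)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"label": self.labels, "count": self.counts, "frequency": self.frequencies}
        )


def preprocess(
    records: pd.DataFrame,
    min_cdr3_aa_len: int = 4,
    min_occurrence: int = 2,
) -> pd.DataFrame:
    """Standard repertoire preprocessing filter.

    Keeps productive records whose CDR3 has at least ``min_cdr3_aa_len``
    amino acids and whose CDR3 occurs at least ``min_occurrence`` times
    within its chain (heavy / kappa / lambda). Idempotent.
    """
    if records.empty:
        return records.copy()
    df = records[records["productive"].astype(bool)].copy()
    df = df[df["cdr3_aa"].str.len() >= min_cdr3_aa_len]
    if min_occurrence > 1 and not df.empty:
        occ = df.groupby(["locus", "cdr3_aa"])["cdr3_aa"].transform("size")
        df = df[occ >= min_occurrence]
    return df.reset_index(drop=True)


def _paired_light(records: pd.DataFrame) -> pd.DataFrame:
    """One productive light-chain record per cell (best-scoring if several)."""
    light = records[
        records["locus"].isin(["IGK", "IGL"]) & records["productive"].astype(bool)
    ].copy()
    if light.empty:
        return light
    light["_score"] = light["v_score"] + light["j_score"]
    light = light.sort_values(["cell_id", "_score"], ascending=[True, False])
    return light.drop_duplicates("cell_id", keep="first").drop(columns="_score")


def isotype_family_frequencies(
    records: pd.DataFrame, gs: GermlineSet
) -> tuple[UsageTable, UsageTable]:
    """Kappa/lambda isotype shares and lambda-family shares, per cell.

    Cells without a productive light chain are excluded (they correspond
    to surface-BCR-negative cells). Lambda families are assigned from the
    J call through the J-C linkage map.
    """
    light = _paired_light(records)
    iso_counts = [
        int((light["locus"] == "IGK").sum()),
        int((light["locus"] == "IGL").sum()),
    ]
    iso = UsageTable("isotype", None, ["kappa", "lambda"], np.array(iso_counts))
    fam_map = gs.lambda_family_of
    lam = light[light["locus"] == "IGL"]
    fams = ["lambda1", "lambda2", "lambda3"]
    fam_counts = np.zeros(3, dtype=np.int64)
    for j_call, n in lam["j_call"].value_counts().items():
        f = fam_map.get(j_call)
        if f in fams:
            fam_counts[fams.index(f)] += n
    fam = UsageTable("lambda_family", "IGL", fams, fam_counts)
    return iso, fam


def gene_usage(
    records: pd.DataFrame,
    axis: str,
    locus: str,
    gs: GermlineSet | None = None,
) -> UsageTable:
    """Per-gene relative frequency among productive records of a locus.

    ``axis`` is ``"v_gene"`` or ``"j_gene"``. When a germline set is given,
    all functional genes of that class appear as labels (zero-filled);
    otherwise labels are the genes observed.
    """
    if axis not in ("v_gene", "j_gene"):
        raise ValueError(f"unsupported axis {axis!r}")
    col = "v_call" if axis == "v_gene" else "j_call"
    sub = records[
        (records["locus"] == locus) & records["productive"].astype(bool)
    ]
    counts = sub[col].value_counts()
    if gs is not None:
        cls = SegmentClass.V if axis == "v_gene" else SegmentClass.J
        labels = [
            s.name for s in gs.by_class(Locus(locus), cls, functional_only=True)
        ]
    else:
        labels = sorted(counts.index)
    arr = np.array([int(counts.get(l, 0)) for l in labels], dtype=np.int64)
    return UsageTable(axis, locus, labels, arr)


def pearson_usage(a: UsageTable, b: UsageTable) -> tuple[float, float]:
    """Pearson correlation between two usage frequency vectors.

    Label sets are union-aligned with zero frequencies for absent genes;
    the p-value is two-tailed from the t distribution with n-2 df.
    """
    labels = sorted(set(a.labels) | set(b.labels))
    if len(labels) < 3:
        raise ValueError("Pearson correlation needs at least 3 labels")

    def vec(t: UsageTable) -> np.ndarray:
        f = dict(zip(t.labels, t.frequencies))
        return np.array([f.get(l, 0.0) for l in labels])

    r, p = sps.pearsonr(vec(a), vec(b))
    return float(r), float(p)


def vj_pairing_matrix(
    records: pd.DataFrame, locus: str, gs: GermlineSet | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """V x J pair counts, row-normalised frequencies, cross-cassette mass.

    Cross-cassette mass (Igl only, else NaN) is the fraction of records
    whose V-J combination crosses the cassette boundary.
    """
    sub = records[
        (records["locus"] == locus) & records["productive"].astype(bool)
    ]
    counts = pd.crosstab(sub["v_call"], sub["j_call"])
    counts.index.name, counts.columns.name = "v_call", "j_call"
    row_freq = counts.div(counts.sum(axis=1).replace(0, np.nan), axis=0).fillna(0.0)
    cross_mass = float("nan")
    if locus == "IGL" and gs is not None and len(sub):
        cross = 0
        for (v, j), n in sub.groupby(["v_call", "j_call"]).size().items():
            if cassette_of(gs, v, j) == "cross_cassette":
                cross += n
        cross_mass = cross / len(sub)
    return counts, row_freq, cross_mass


def editing_signature(records: pd.DataFrame) -> tuple[UsageTable, float]:
    """Igk J-gene usage and the Igkj5 share (receptor-editing signature).

    A raised Igkj5 share marks increased secondary Igk V-to-J
    rearrangements, the hallmark of receptor editing short of RS deletion.
    """
    table = gene_usage(records, "j_gene", "IGK")
    if table.empty:
        return table, float("nan")
    jk5 = table["Igkj5"] if "Igkj5" in table.labels else 0.0
    return table, jk5


DEFAULT_POSITIVE = frozenset("RK")
DEFAULT_NEGATIVE = frozenset("DE")


def cdr3_properties(
    records: pd.DataFrame, include_histidine: bool = False
) -> pd.DataFrame:
    """Per-record CDR3 length and net charge, tagged by chain.

    Net charge is #(R,K) - #(D,E) at approximately neutral pH; histidine
    counts as +1 only when ``include_histidine`` is set.
    """
    pos = DEFAULT_POSITIVE | ({"H"} if include_histidine else set())
    rows = []
    for _, rec in records.iterrows():
        cdr3 = rec["cdr3_aa"]
        if not cdr3:
            continue
        charge = sum(c in pos for c in cdr3) - sum(c in DEFAULT_NEGATIVE for c in cdr3)
        rows.append(
            {
                "cell_id": rec["cell_id"],
                "chain": CHAIN_OF_LOCUS.get(rec["locus"], "other"),
                "cdr3_aa": cdr3,
                "length": len(cdr3),
                "charge": charge,
            }
        )
    return pd.DataFrame(rows, columns=["cell_id", "chain", "cdr3_aa", "length", "charge"])


def summarize_cdr3(props: pd.DataFrame) -> pd.DataFrame:
    """Mean/median length and charge per chain."""
    if props.empty:
        return pd.DataFrame()
    return props.groupby("chain")[["length", "charge"]].agg(["mean", "median"])


def clonotype_table(
    records: pd.DataFrame, definition: str = "heavy_cdr3"
) -> pd.DataFrame:
    """Clonotype frequency table (treemap-ready), sorted descending.

    Definitions: ``heavy_cdr3`` / ``kappa_cdr3`` / ``lambda_cdr3`` use the
    unique CDR3 of that chain; ``paired_hl`` keys each cell by its
    (heavy CDR3, light CDR3) combination.
    """
    if definition == "paired_hl":
        heavy = records[
            (records["locus"] == "IGH") & records["productive"].astype(bool)
        ][["cell_id", "cdr3_aa"]].drop_duplicates("cell_id")
        light = _paired_light(records)[["cell_id", "cdr3_aa"]]
        merged = heavy.merge(light, on="cell_id", suffixes=("_heavy", "_light"))
        keys = merged["cdr3_aa_heavy"] + "|" + merged["cdr3_aa_light"]
    else:
        locus = {"heavy_cdr3": "IGH", "kappa_cdr3": "IGK", "lambda_cdr3": "IGL"}.get(
            definition
        )
        if locus is None:
            raise ValueError(f"unknown clonotype definition {definition!r}")
        keys = records[
            (records["locus"] == locus) & records["productive"].astype(bool)
        ]["cdr3_aa"].astype(str)
        keys = keys[keys.str.len() > 0]
    counts = keys.value_counts()
    out = pd.DataFrame(
        {
            "key": counts.index,
            "count": counts.to_numpy(),
            "frequency": (counts / counts.sum()).to_numpy() if len(counts) else [],
        }
    )
    return out.reset_index(drop=True)


def productivity_fractions(raw: pd.DataFrame) -> pd.DataFrame:
    """Per-locus failure-mode shares over the unfiltered annotation table.

    Reads that received no locus (decoys, orphon-like) form the ``non_ig``
    pool. Within each locus the shares of {none, out_of_frame, stop_codon}
    sum to 1; ``unproductive`` is their sum minus the productive share.
    """
    if raw.empty:
        return pd.DataFrame(
            columns=["locus", "n_reads", "productive", "out_of_frame", "stop_codon", "unproductive"]
        )
    df = raw.copy()
    df["_pool"] = np.where(df["locus"] == "", "non_ig", df["locus"])
    weights = df["duplicate_count"] if "duplicate_count" in df else 1
    df["_w"] = weights
    rows = []
    for pool, grp in df.groupby("_pool"):
        n = grp["_w"].sum()
        share = lambda mode: float(grp.loc[grp["failure_mode"] == mode, "_w"].sum() / n)
        prod = float(grp.loc[grp["productive"].astype(bool), "_w"].sum() / n)
        rows.append(
            {
                "locus": pool,
                "n_reads": int(n),
                "productive": prod,
                "out_of_frame": share("out_of_frame"),
                "stop_codon": share("stop_codon"),
                "unproductive": 1.0 - prod,
            }
        )
    return pd.DataFrame(rows).sort_values("locus").reset_index(drop=True)
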
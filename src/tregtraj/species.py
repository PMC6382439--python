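"""Cross-species comparison of non-lymphoid-tissue marker signatures.

Marker tables from two species are linked through one-to-one orthologs:
the overlap operation counts markers conserved through orthology, the
fold-change concordance joins per-gene NLT-vs-LT log fold-changes, and the
paralog-substitution detector flags within-family swaps of the NLT-marker
role — gene g is a significant NLT marker in species A while essentially
unexpressed in species B's NLT cells, and a paralog g' of the same family
shows the mirror pattern (the Pim1/Pim2-style event).  "Not expressed" is
operationalised as detection in fewer than ``silent_frac`` (default 5%) of
the relevant NLT cells.

Ortholog/paralog maps are TSV inputs (columns gene_a, gene_b,
homology_type, family_id); gene identifiers are matched case-insensitively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "read_homology_map",
    "marker_overlap",
    "fold_change_concordance",
    "detect_paralog_substitution",
    "SubstitutionPair",
]


def read_homology_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_a", "gene_b"}
    if not required <= set(df.columns):
        raise ValueError("homology map needs gene_a and gene_b columns")
    return df


def _norm(genes):
    return {str(g).upper() for g in genes}


def _one2one(omap: pd.DataFrame) -> pd.DataFrame:
    if "homology_type" in omap.columns:
        omap = omap[omap["homology_type"] == "one2one"]
    m = omap.assign(
        gene_a=omap["gene_a"].astype(str).str.upper(),
        gene_b=omap["gene_b"].astype(str).str.upper(),
    )
    if m["gene_a"].duplicated().any() or m["gene_b"].duplicated().any():
        m = m[~m["gene_a"].duplicated(keep=False) & ~m["gene_b"].duplicated(keep=False)]
    return m


def _marker_genes(markers) -> set:
    if isinstance(markers, pd.DataFrame):
        if "significant" in markers.columns:
            markers = markers.loc[markers["significant"], "gene"]
        else:
            markers = markers["gene"]
    return _norm(markers)


def marker_overlap(markers_a, markers_b, omap: pd.DataFrame) -> dict:
    """Markers shared between species through one-to-one orthology.

    Returns counts restricted to mapped genes (n_a, n_b), the number
    shared, and the shared ortholog pairs.
    """
    m = _one2one(omap)
    if not len(m):
        raise ValueError("empty ortholog map")
    a = _marker_genes(markers_a) & set(m["gene_a"])
    b = _marker_genes(markers_b) & set(m["gene_b"])
    a2b = dict(zip(m["gene_a"], m["gene_b"]))
    shared = sorted((g, a2b[g]) for g in a if a2b[g] in b)
    return {"n_a": len(a), "n_b": len(b), "n_shared": len(shared), "shared": shared}


def fold_change_concordance(de_a: pd.DataFrame, de_b: pd.DataFrame,
                            omap: pd.DataFrame) -> dict:
    """Join per-gene NLT-vs-LT fold-changes across species.

    Both DE tables need gene and avg_logFC columns.  Returns the joined
    table and the fraction of ortholog pairs with concordant fold-change
    sign.
    """
    m = _one2one(omap)
    fa = de_a.assign(gene=de_a["gene"].astype(str).str.upper()).set_index("gene")["avg_logFC"]
    fb = de_b.assign(gene=de_b["gene"].astype(str).str.upper()).set_index("gene")["avg_logFC"]
    rows = [
        (ga, gb, fa[ga], fb[gb])
        for ga, gb in zip(m["gene_a"], m["gene_b"])
        if ga in fa.index and gb in fb.index
    ]
    if not rows:
        raise ValueError("no joinable genes between the DE tables")
    table = pd.DataFrame(rows, columns=["gene_a", "gene_b", "logFC_a", "logFC_b"])
    nonzero = (table["logFC_a"] != 0) & (table["logFC_b"] != 0)
    conc = float((np.sign(table.loc[nonzero, "logFC_a"])
                  == np.sign(table.loc[nonzero, "logFC_b"])).mean()) if nonzero.any() else float("nan")
    return {"table": table, "concordance": conc, "n_pairs": len(table)}


@dataclass
class SubstitutionPair:
    """A within-family swap of the NLT-marker role between species."""

    gene_a: str
    paralog_b: str
    family_id: str
    pct_nlt_a_gene_a: float
    pct_nlt_b_gene_a: float
    pct_nlt_b_paralog: float
    pct_nlt_a_paralog: float


def detect_paralog_substitution(stats_a: pd.DataFrame, stats_b: pd.DataFrame,
                                markers_a, markers_b, families: pd.DataFrame,
                                silent_frac: float = 0.05) -> pd.DataFrame:
    """Flag paralog-substitution events between species.

    ``stats_a``/``stats_b`` give the fraction of NLT cells expressing each
    gene (columns gene, pct_nlt); ``families`` lists paralog family members
    as ortholog pairs (columns gene_a, gene_b, family_id).  An event
    (g, g') is reported when g is a significant NLT marker in species A and
    detected in < silent_frac of species B's NLT cells, while the family
    paralog g' is the mirror case.
    """
    ma, mb = _marker_genes(markers_a), _marker_genes(markers_b)
    pa = stats_a.assign(gene=stats_a["gene"].astype(str).str.upper()).set_index("gene")["pct_nlt"]
    pb = stats_b.assign(gene=stats_b["gene"].astype(str).str.upper()).set_index("gene")["pct_nlt"]
    fam = families.assign(
        gene_a=families["gene_a"].astype(str).str.upper(),
        gene_b=families["gene_b"].astype(str).str.upper(),
    )
    if "family_id" not in fam.columns:
        raise ValueError("families table needs a family_id column")
    rows = []
    for fid, members in fam.groupby("family_id"):
        pairs = list(zip(members["gene_a"], members["gene_b"]))
        usable = []
        for ga, gb in pairs:
            if ga not in pa.index or gb not in pb.index:
                warnings.warn(f"family {fid!r}: {ga}/{gb} missing expression stats; skipped")
                continue
            usable.append((ga, gb))
        for ga_i, gb_i in usable:
            for ga_j, gb_j in usable:
                if ga_i == ga_j:
                    continue
                if (ga_i in ma and pb[gb_i] < silent_frac
                        and gb_j in mb and pa[ga_j] < silent_frac):
                    rows.append(SubstitutionPair(
                        gene_a=ga_i, paralog_b=gb_j, family_id=str(fid),
                        pct_nlt_a_gene_a=float(pa[ga_i]),
                        pct_nlt_b_gene_a=float(pb[gb_i]),
                        pct_nlt_b_paralog=float(pb[gb_j]),
                        pct_nlt_a_paralog=float(pa[ga_j]),
                    ))
    return pd.DataFrame([vars(r) for r in rows],
                        columns=["gene_a", "paralog_b", "family_id",
                                 "pct_nlt_a_gene_a", "pct_nlt_b_gene_a",
                                 "pct_nlt_b_paralog", "pct_nlt_a_paralog"])
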
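"""Interval algebra for the feature universe of the time-course analysis.

Defines the region classes the counting is done over: consensus ChIP
peaks across replicates, active genes (TSS overlapping both an H3K9ac
and an H3K4me3 consensus peak), promoters (TSS +/- 2 kb), gene bodies
(gene minus the first 2 kb), putative active enhancers
(H3K27ac ∩ H3K4me1, >= 1 kb from any TSS), genome-wide 10-kb windows
and intergenic windows; plus distance/density annotation against anchor
sets (Xist locus, entry sites, TAD boundaries, LADs, LINEs, genes).

All coordinates are 0-based half-open (BED convention) in pandas
frames with columns chrom, start, end (strand where relevant); the
heavy lifting stands on pyranges.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pyranges as pr

__all__ = [
    "read_bed",
    "read_refflat",
    "consensus_peaks",
    "define_active_genes",
    "define_features",
    "tile_windows",
    "annotate_distances",
    "annotate_peak_context",
]

_PR_COLS = {"chrom": "Chromosome", "start": "Start", "end": "End", "strand": "Strand"}


def _to_pr(df: pd.DataFrame) -> pr.PyRanges:
    cols = {k: v for k, v in _PR_COLS.items() if k in df.columns}
    return pr.PyRanges(df.rename(columns=cols))


def _from_pr(g: pr.PyRanges) -> pd.DataFrame:
    df = g.df.rename(columns={v: k for k, v in _PR_COLS.items()})
    if "chrom" in df.columns:
        df["chrom"] = df["chrom"].astype(str)
    return df.reset_index(drop=True)


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
        raise ValueError("intervals must satisfy 0 <= start < end")
    return df


def read_bed(path) -> pd.DataFrame:
    """Read a BED3+ file into a chrom/start/end(/name/score/strand) frame."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : min(6, df.shape[1])]
    df.columns = names[: df.shape[1]]
    df["chrom"] = df["chrom"].astype(str)
    return _validate(df)


def read_refflat(path) -> pd.DataFrame:
    """Read a refFlat annotation into a transcript table with TSS.

    Columns gene, transcript, chrom, strand, tx_start, tx_end plus a
    strand-aware ``tss`` (tx_start for +, tx_end - 1 for -; 0-based).
    """
    names = [
        "gene", "transcript", "chrom", "strand",
        "tx_start", "tx_end", "cds_start", "cds_end",
        "exon_count", "exon_starts", "exon_ends",
    ]
    df = pd.read_csv(path, sep="\t", header=None, names=names)
    df["chrom"] = df["chrom"].astype(str)
    if (df["tx_start"] >= df["tx_end"]).any():
        raise ValueError("refFlat transcripts must satisfy tx_start < tx_end")
    df["tss"] = np.where(df["strand"] == "-", df["tx_end"] - 1, df["tx_start"])
    return df


def _merge(df: pd.DataFrame) -> pd.DataFrame:
    return _from_pr(_to_pr(df[["chrom", "start", "end"]]).merge())


def consensus_peaks(
    replicate_peak_sets: list[pd.DataFrame],
    fc_values: list | None = None,
    min_fc: float = 3.0,
    mode: str = "intersect",
    k: int = 2,
) -> pd.DataFrame:
    """Consensus peak regions across replicate peak sets.

    Peaks with fold change < ``min_fc`` are removed first (when
    ``fc_values`` supplies one array per replicate set).  Then either
    mode="intersect": merge each replicate's peaks and keep the common
    regions of all replicates (the duplicate design), or mode="k_of_n":
    keep regions covered by at least ``k`` of the sets (the >= 2-of-4
    FLAG design).
    """
    if not replicate_peak_sets:
        raise ValueError("need at least one replicate peak set")
    sets = []
    for i, peaks in enumerate(replicate_peak_sets):
        peaks = _validate(peaks.copy())
        if fc_values is not None:
            fc = np.asarray(fc_values[i], dtype=float)
            peaks = peaks[fc >= min_fc]
        if peaks.empty:
            if mode == "intersect":
                return pd.DataFrame(columns=["chrom", "start", "end"])
            continue
        sets.append(_merge(peaks))
    if mode == "intersect":
        g = _to_pr(sets[0])
        for other in sets[1:]:
            g = g.intersect(_to_pr(other))
            if len(g) == 0:
                return pd.DataFrame(columns=["chrom", "start", "end"])
        return _from_pr(g.merge())
    if mode == "k_of_n":
        if not sets:
            return pd.DataFrame(columns=["chrom", "start", "end"])
        named = {f"s{i}": _to_pr(s) for i, s in enumerate(sets)}
        cov = pr.count_overlaps(named).df
        cov["n"] = cov[[f"s{i}" for i in range(len(sets))]].sum(axis=1)
        hit = cov[cov["n"] >= k][["Chromosome", "Start", "End"]]
        if hit.empty:
            return pd.DataFrame(columns=["chrom", "start", "end"])
        return _from_pr(pr.PyRanges(hit).merge())
    raise ValueError("mode must be 'intersect' or 'k_of_n'")


def _tss_points(transcripts: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": transcripts["chrom"],
            "start": transcripts["tss"],
            "end": transcripts["tss"] + 1,
        }
    )


def define_active_genes(
    transcripts: pd.DataFrame,
    h3k9ac_peaks: pd.DataFrame,
    h3k4me3_peaks: pd.DataFrame,
) -> pd.DataFrame:
    """Genes with a TSS inside both an H3K9ac and an H3K4me3 consensus peak.

    The active gene span runs from the minimum start to the maximum end
    over the gene's active transcripts; strand is taken from the
    transcripts.
    """
    tss = _to_pr(_tss_points(transcripts))
    in9 = tss.count_overlaps(_to_pr(h3k9ac_peaks), overlap_col="n9").df["n9"] > 0
    in4 = tss.count_overlaps(_to_pr(h3k4me3_peaks), overlap_col="n4").df["n4"] > 0
    active_tx = transcripts[np.asarray(in9) & np.asarray(in4)]
    if active_tx.empty:
        return pd.DataFrame(columns=["gene", "chrom", "start", "end", "strand"])
    genes = (
        active_tx.groupby("gene")
        .agg(
            chrom=("chrom", "first"),
            start=("tx_start", "min"),
            end=("tx_end", "max"),
            strand=("strand", "first"),
        )
        .reset_index()
    )
    return genes


def tile_windows(chrom_sizes: dict, width: int = 10_000) -> pd.DataFrame:
    """Fixed-width windows partitioning each chromosome (last truncated)."""
    if width <= 0:
        raise ValueError("window width must be positive")
    rows = []
    for chrom, size in chrom_sizes.items():
        starts = np.arange(0, size, width)
        for s in starts:
            rows.append({"chrom": str(chrom), "start": int(s), "end": int(min(s + width, size))})
    return pd.DataFrame(rows)


def _promoters(genes: pd.DataFrame, chrom_sizes: dict | None, flank: int) -> pd.DataFrame:
    tss = np.where(genes["strand"] == "-", genes["end"] - 1, genes["start"])
    start = np.maximum(tss - flank, 0)
    end = tss + flank
    if chrom_sizes:
        caps = genes["chrom"].map(chrom_sizes)
        end = np.minimum(end, caps.fillna(np.inf)).astype(int)
    return pd.DataFrame(
        {"gene": genes["gene"], "chrom": genes["chrom"], "start": start, "end": end,
         "strand": genes["strand"]}
    )


def _gene_bodies(genes: pd.DataFrame, skip: int) -> pd.DataFrame:
    plus = genes["strand"] != "-"
    start = np.where(plus, genes["start"] + skip, genes["start"])
    end = np.where(plus, genes["end"], genes["end"] - skip)
    bodies = pd.DataFrame(
        {"gene": genes["gene"], "chrom": genes["chrom"], "start": start, "end": end,
         "strand": genes["strand"]}
    )
    return bodies[bodies["start"] < bodies["end"]].reset_index(drop=True)


def define_features(
    active_genes: pd.DataFrame,
    all_genes: pd.DataFrame | None = None,
    h3k27ac_consensus: pd.DataFrame | None = None,
    h3k4me1_consensus: pd.DataFrame | None = None,
    transcripts: pd.DataFrame | None = None,
    chrom_sizes: dict | None = None,
    promoter_flank: int = 2000,
    body_skip: int = 2000,
    enhancer_min_tss_distance: int = 1000,
    window_width: int = 10_000,
) -> dict[str, pd.DataFrame]:
    """Derive the counting regions from active genes and consensus peaks.

    promoters: TSS +/- promoter_flank (strand-aware, clipped at
    chromosome bounds); gene_bodies: active gene minus its first
    body_skip bp downstream of the TSS; enhancers:
    H3K27ac ∩ H3K4me1 consensus regions at least
    ``enhancer_min_tss_distance`` from any TSS (all transcripts by
    default); intergenic_windows: genome tiles overlapping no gene
    (active or not, extended by the promoter region upstream of its
    TSS) and no enhancer.  Pieces whose inputs are not supplied are
    omitted from the result dict.
    """
    out: dict[str, pd.DataFrame] = {}
    out["promoters"] = _promoters(active_genes, chrom_sizes, promoter_flank)
    out["gene_bodies"] = _gene_bodies(active_genes, body_skip)

    tss_pts = None
    if transcripts is not None:
        tss_pts = _tss_points(transcripts)
    elif len(active_genes):
        tss = np.where(
            active_genes["strand"] == "-", active_genes["end"] - 1, active_genes["start"]
        )
        tss_pts = pd.DataFrame(
            {"chrom": active_genes["chrom"], "start": tss, "end": tss + 1}
        )

    if h3k27ac_consensus is not None and h3k4me1_consensus is not None:
        enh = _to_pr(h3k27ac_consensus).intersect(_to_pr(h3k4me1_consensus)).merge()
        enh_df = _from_pr(enh) if len(enh) else pd.DataFrame(columns=["chrom", "start", "end"])
        if len(enh_df) and tss_pts is not None and len(tss_pts):
            near = _to_pr(enh_df).nearest(_to_pr(tss_pts)).df
            keep = near["Distance"].to_numpy() >= enhancer_min_tss_distance
            enh_df = _from_pr(
                pr.PyRanges(near[keep][["Chromosome", "Start", "End"]])
            ) if keep.any() else pd.DataFrame(columns=["chrom", "start", "end"])
        out["enhancers"] = enh_df.reset_index(drop=True)

    if chrom_sizes is not None:
        windows = tile_windows(chrom_sizes, window_width)
        exclusion = []
        genes_all = all_genes if all_genes is not None else active_genes
        if len(genes_all):
            ext_start = np.where(
                genes_all["strand"] == "-", genes_all["start"],
                np.maximum(genes_all["start"] - promoter_flank, 0),
            )
            ext_end = np.where(
                genes_all["strand"] == "-", genes_all["end"] + promoter_flank,
                genes_all["end"],
            )
            exclusion.append(
                pd.DataFrame(
                    {"chrom": genes_all["chrom"], "start": ext_start, "end": ext_end}
                )
            )
        if "enhancers" in out and len(out["enhancers"]):
            exclusion.append(out["enhancers"][["chrom", "start", "end"]])
        if exclusion:
            excl = pd.concat(exclusion, ignore_index=True)
            gw = _to_pr(windows)
            hits = gw.count_overlaps(_to_pr(excl), overlap_col="n_excl").df
            clean = hits[hits["n_excl"] == 0][["Chromosome", "Start", "End"]]
            out["intergenic_windows"] = _from_pr(pr.PyRanges(clean)) if len(clean) else (
                pd.DataFrame(columns=["chrom", "start", "end"])
            )
        else:
            out["intergenic_windows"] = windows
    return out


def _midpoints(features: pd.DataFrame) -> np.ndarray:
    return ((features["start"] + features["end"]) // 2).to_numpy()


def annotate_distances(
    features: pd.DataFrame,
    anchors: dict[str, pd.DataFrame] | None = None,
    densities: dict[str, pd.DataFrame] | None = None,
    window: int = 100_000,
    entry_site_key: str = "entry_site",
    proximity: int = 100_000,
) -> pd.DataFrame:
    """Distance and density annotation of features against anchor sets.

    Per feature: midpoint distance to the nearest interval of each
    anchor set (columns ``dist_<name>``; nan and a note when a set is
    empty), the fraction of a ``window``-bp neighbourhood around the
    midpoint covered by each density set (``density_<name>``), and a
    ``near_entry_site`` flag when an anchor named ``entry_site_key`` is
    given (distance < ``proximity``).
    """
    out = features.reset_index(drop=True).copy()
    mids = _midpoints(out)
    pts = pd.DataFrame({"chrom": out["chrom"], "start": mids, "end": mids + 1})
    pts_pr = pr.PyRanges(
        pts.rename(columns=_PR_COLS).assign(_row=np.arange(len(pts)))
    )
    for name, anc in (anchors or {}).items():
        col = f"dist_{name}"
        if anc is None or len(anc) == 0:
            out[col] = np.nan
            continue
        near = pts_pr.nearest(_to_pr(anc[["chrom", "start", "end"]])).df
        dist = pd.Series(np.nan, index=out.index)
        if len(near):
            dist.loc[near["_row"].to_numpy()] = near["Distance"].to_numpy(float)
        out[col] = dist
        if name == entry_site_key:
            out["near_entry_site"] = dist < proximity
    for name, elems in (densities or {}).items():
        col = f"density_{name}"
        if elems is None or len(elems) == 0:
            out[col] = np.nan
            continue
        half = window // 2
        neigh = pd.DataFrame(
            {
                "chrom": out["chrom"],
                "start": np.maximum(mids - half, 0),
                "end": mids + half,
            }
        )
        npr = pr.PyRanges(
            neigh.rename(columns=_PR_COLS).assign(_row=np.arange(len(neigh)))
        )
        inter = npr.intersect(_to_pr(_merge(elems[["chrom", "start", "end"]]))).df
        cov = pd.Series(0.0, index=out.index)
        if len(inter):
            bases = (inter["End"] - inter["Start"]).groupby(inter["_row"]).sum()
            cov.loc[bases.index] = bases.to_numpy(float)
        out[col] = cov / (neigh["end"] - neigh["start"])
    return out


def annotate_peak_context(
    peaks: pd.DataFrame,
    transcripts: pd.DataFrame,
    gene_bodies: pd.DataFrame,
    promoter_distance: int = 2000,
) -> pd.DataFrame:
    """Label peaks as promoter / intragenic / intergenic.

    A peak within ``promoter_distance`` bp of a TSS (edge-to-point) is
    a promoter peak; otherwise it is intragenic if it overlaps a gene
    body, else intergenic.
    """
    out = peaks.reset_index(drop=True).copy()
    ppr = pr.PyRanges(
        out[["chrom", "start", "end"]]
        .rename(columns=_PR_COLS)
        .assign(_row=np.arange(len(out)))
    )
    labels = np.array(["intergenic"] * len(out), dtype=object)
    if len(gene_bodies):
        hit = ppr.count_overlaps(_to_pr(gene_bodies), overlap_col="n").df
        rows = hit.loc[hit["n"] > 0, "_row"].to_numpy()
        labels[rows] = "intragenic"
    tss_pts = _tss_points(transcripts)
    if len(tss_pts):
        near = ppr.nearest(_to_pr(tss_pts)).df
        close = near.loc[near["Distance"] < promoter_distance, "_row"].to_numpy()
        labels[close] = "promoter"
    out["context"] = labels
    return out
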
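"""Assign long reads to haplotypes from phased SNVs and split the read set.

A read votes at every phased heterozygous SNV it covers; the tag is the
haplotype with the larger agreement count, and strict ties (including zero
informative sites) leave the read untagged.  Splitting partitions reads
exactly into {h1, h2, untagged}; the "-un" sets used for haploid assembly
duplicate the untagged reads into both haplotype bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .strandphase import HaplotypeBlock

H1, H2, UNTAGGED = 1, 2, 0


def haplotag_reads(lr_alleles: pd.DataFrame, blocks: dict,
                   read_ids=None) -> pd.DataFrame:
    """Tag reads against per-cluster phased haplotypes.

    ``blocks`` maps cluster id -> HaplotypeBlock.  Reads covering SNVs of
    several clusters vote within each and take the cluster with the most
    informative sites.  Returns read_id, cluster, n_h1, n_h2, n_sites, tag;
    reads covering no phased SNV get cluster ``None`` and tag 0.
    """
    parts = []
    for cluster, block in blocks.items():
        col_of = {int(s): i for i, s in enumerate(block.snv_ids)}
        obs = lr_alleles[lr_alleles["snv_id"].isin(col_of)]
        if len(obs) == 0:
            continue
        ci = np.array([col_of[int(s)] for s in obs["snv_id"]])
        phased = block.h1[ci] >= 0
        obs = obs[phased]
        ci = ci[phased]
        if len(obs) == 0:
            continue
        a = obs["allele"].to_numpy()
        df = pd.DataFrame({
            "read_id": obs["read_id"].to_numpy(),
            "n_h1": (a == block.h1[ci]).astype(int),
            "n_h2": (a == block.h2[ci]).astype(int),
        })
        g = df.groupby("read_id").sum().reset_index()
        g["cluster"] = cluster
        parts.append(g)
    if parts:
        allv = pd.concat(parts, ignore_index=True)
        allv["n_sites"] = allv["n_h1"] + allv["n_h2"]
        allv = (allv.sort_values(["read_id", "n_sites"], ascending=[True, False])
                .drop_duplicates("read_id", keep="first"))
    else:
        allv = pd.DataFrame(columns=["read_id", "n_h1", "n_h2", "cluster", "n_sites"])
    if read_ids is not None:
        base = pd.DataFrame({"read_id": np.asarray(read_ids)})
        allv = base.merge(allv, on="read_id", how="left")
        for col in ("n_h1", "n_h2", "n_sites"):
            allv[col] = pd.to_numeric(allv[col], errors="coerce").fillna(0).astype(int)
        allv["cluster"] = allv["cluster"].where(allv["n_sites"] > 0, None)
    allv["tag"] = np.where(allv["n_h1"] > allv["n_h2"], H1,
                           np.where(allv["n_h2"] > allv["n_h1"], H2, UNTAGGED))
    return allv.reset_index(drop=True)


def split_reads(tags: pd.DataFrame, by_cluster: bool = False,
                discard_unknown: bool = False, include_untagged: bool = False,
                cluster=None) -> dict:
    """Partition tagged reads into haplotype read sets.

    Without ``include_untagged`` returns {"h1", "h2", "untagged"} (an exact
    partition); with it returns {"h1-un", "h2-un"} where untagged reads are
    duplicated into both.  With ``by_cluster`` the split is per cluster; with
    ``discard_unknown`` reads from other clusters (or no cluster) are
    dropped instead of landing in "untagged".
    """
    if tags["read_id"].duplicated().any():
        raise ValueError("duplicate read tags")

    def one_split(sub: pd.DataFrame) -> dict:
        h1 = sub.loc[sub["tag"] == H1, "read_id"].tolist()
        h2 = sub.loc[sub["tag"] == H2, "read_id"].tolist()
        un = sub.loc[sub["tag"] == UNTAGGED, "read_id"].tolist()
        if include_untagged:
            return {"h1-un": h1 + un, "h2-un": h2 + un}
        return {"h1": h1, "h2": h2, "untagged": un}

    if not by_cluster:
        if cluster is not None:
            in_c = tags["cluster"] == cluster
            sub = tags[in_c] if discard_unknown else tags.assign(
                tag=np.where(in_c, tags["tag"], UNTAGGED))
        else:
            sub = tags
        return one_split(sub)
    out = {}
    for cl in sorted(c for c in tags["cluster"].dropna().unique()):
        in_c = tags["cluster"] == cl
        sub = tags[in_c] if discard_unknown else tags.assign(
            tag=np.where(in_c, tags["tag"], UNTAGGED))
        out[cl] = one_split(sub)
    return out
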
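"""Population-genetic summaries of copy number.

V_st is the copy-number analogue of F_st:

    V_st = (V_tot - V_pop) / V_tot

with V_tot the variance in copy number over the pooled individuals of a
population pair and V_pop the (unweighted) mean of the two within-population
variances. V_st is undefined (NaN) when V_tot = 0 and may be negative; raw
values are reported unclamped so outlier ranking is preserved.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .config import PipelineConfig
from .errors import DataError


@dataclass
class VstResult:
    unit_id: str
    pop_a: str
    pop_b: str
    v_tot: float
    v_pop: float
    vst: float  # NaN when v_tot == 0


def vst(copy_numbers, population_labels, pair, unbiased: bool = True,
        weighted: bool = False, unit_id: str = "") -> VstResult:
    """V_st between one population pair at one region/gene.

    Parameters use the unbiased (n-1) variance estimator by default;
    ``weighted=True`` weights V_pop by population sample sizes instead of
    averaging the two variances.
    """
    cn = np.asarray(copy_numbers, dtype=float)
    labels = np.asarray(population_labels)
    a, b = pair
    xa, xb = cn[labels == a], cn[labels == b]
    if len(xa) < 2 or len(xb) < 2:
        raise DataError(f"population pair ({a}, {b}) needs >=2 samples per population")
    ddof = 1 if unbiased else 0
    pooled = np.concatenate([xa, xb])
    v_tot = float(np.var(pooled, ddof=ddof))
    va, vb = float(np.var(xa, ddof=ddof)), float(np.var(xb, ddof=ddof))
    if weighted:
        v_pop = (len(xa) * va + len(xb) * vb) / (len(xa) + len(xb))
    else:
        v_pop = (va + vb) / 2.0
    v = (v_tot - v_pop) / v_tot if v_tot > 0 else float("nan")
    return VstResult(unit_id, a, b, v_tot, v_pop, v)


def vst_scan(cn: pd.DataFrame, metadata: pd.DataFrame,
             config: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All pairwise-population V_st per region plus the outlier set.

    Outliers are the records in the top ``vst_top_fraction`` of all pairwise
    V_st values pooled over pairs *and* above ``vst_floor``; ties at the
    rank cutoff are included.
    """
    pops = sorted(metadata["population"].unique())
    if len(pops) < 2:
        raise DataError("V_st scan needs at least 2 populations")
    labels = metadata.set_index("sample")["population"].reindex(cn.columns).to_numpy()
    rows = []
    for region_id, row in cn.iterrows():
        x = row.to_numpy(dtype=float)
        for a, b in itertools.combinations(pops, 2):
            r = vst(x, labels, (a, b), unbiased=config.vst_unbiased,
                    weighted=config.vst_weighted, unit_id=str(region_id))
            rows.append((r.unit_id, r.pop_a, r.pop_b, r.v_tot, r.v_pop, r.vst))
    table = pd.DataFrame(rows, columns=["region_id", "pop_a", "pop_b",
                                        "v_tot", "v_pop", "vst"])
    finite = table["vst"].dropna()
    if len(finite):
        n_top = max(1, math.ceil(config.vst_top_fraction * len(finite)))
        cutoff = np.sort(finite.to_numpy())[-n_top]
        outliers = table[(table["vst"] >= cutoff) & (table["vst"] > config.vst_floor)]
    else:
        outliers = table.iloc[0:0]
    return table, outliers.reset_index(drop=True)


def cnv_frequencies(cn: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Allele frequency and carrier count per region per population.

    Only bi-allelic loci enter the table: deletion loci with states within
    {0,1,2} (frequency of the deleted allele = (2*n0 + n1)/2n) and
    duplication loci with states within {2,3,4} (frequency of the gained
    allele = (2*n4 + n3)/2n). Loci mixing deletion and duplication states,
    or exceeding copy number 4, are excluded.
    """
    pop = metadata.set_index("sample")["population"].reindex(cn.columns)
    rows = []
    for region_id, row in cn.iterrows():
        states = set(int(v) for v in row)
        if states <= {0, 1, 2}:
            kind, low = "deletion", True
        elif states <= {2, 3, 4}:
            kind, low = "duplication", False
        else:
            continue
        for p, sub in row.groupby(pop):
            x = sub.to_numpy(dtype=int)
            n = len(x)
            if low:
                freq = (2 * np.sum(x == 0) + np.sum(x == 1)) / (2 * n)
            else:
                freq = (2 * np.sum(x == 4) + np.sum(x == 3)) / (2 * n)
            rows.append((region_id, kind, p, int(np.sum(x != 2)), float(freq)))
    return pd.DataFrame(rows, columns=["region_id", "cnv_class", "population",
                                       "carrier_count", "allele_frequency"])


def sharing_summary(cn: pd.DataFrame, metadata: pd.DataFrame) -> dict:
    """Sharing of CNVs across populations (UpSet-style) and singletons.

    Presence of a CNV in a sample means any copy number != 2. Returns a
    dict with an ``intersections`` table (one row per exact population
    subset carrying the CNV), ``singleton_count`` (CNVs carried by exactly
    one individual) and ``singleton_proportion``.
    """
    pop = metadata.set_index("sample")["population"].reindex(cn.columns).to_numpy()
    present = cn.to_numpy() != 2
    subsets: dict[tuple, int] = {}
    singleton = 0
    for i in range(len(cn)):
        carriers = present[i]
        if not carriers.any():
            continue
        if carriers.sum() == 1:
            singleton += 1
        key = tuple(sorted(set(pop[carriers])))
        subsets[key] = subsets.get(key, 0) + 1
    inter = pd.DataFrame(
        [(";".join(k), len(k), v) for k, v in sorted(subsets.items())],
        columns=["populations", "n_populations", "n_cnvs"])
    total = int((present.any(axis=1)).sum())
    return {"intersections": inter,
            "singleton_count": singleton,
            "singleton_proportion": singleton / total if total else float("nan"),
            "n_cnvs_with_carriers": total}


def pca_presence(matrix: pd.DataFrame, n_components: int | None = None) -> dict:
    """Centered PCA of samples over complete-case features.

    ``matrix`` is features x samples (presence/absence or methylation
    levels); features with any missing value are dropped first. Returns
    sample coordinates and the variance-explained ratios (deterministic up
    to sign).
    """
    complete = matrix.dropna(axis=0)
    if complete.shape[0] < 2:
        raise DataError("PCA needs at least 2 complete-case features")
    x = complete.to_numpy(dtype=float).T  # samples x features
    n_comp = n_components or min(x.shape[0] - 1, x.shape[1])
    if n_comp < 1:
        raise DataError("PCA needs at least 2 samples")
    pca = PCA(n_components=n_comp, svd_solver="full")
    coords = pca.fit_transform(x)
    return {"coordinates": pd.DataFrame(
                coords, index=matrix.columns,
                columns=[f"PC{i+1}" for i in range(coords.shape[1])]),
            "explained_variance_ratio": pca.explained_variance_ratio_,
            "n_features_used": complete.shape[0]}
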
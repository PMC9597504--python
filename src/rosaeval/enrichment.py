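"""Pathway over-representation of differential volatile compounds.

Differential compounds from the VIP/fold-change screen are tested against
a compound-to-pathway annotation map with the one-sided hypergeometric
test (the standard over-representation analysis in metabolomics), using
all compounds detected in the experiment as the background universe.
Benjamini-Hochberg FDR values accompany the raw p-values. A per-pathway
stage-trend report summarizes when each member compound peaks over the
four flower-development stages.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError


def hypergeom_upper(k: int, big_k: int, n: int, big_n: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    ``X`` counts annotated compounds in a draw of ``n`` differential
    compounds from a universe of ``big_n`` detected compounds of which
    ``big_k`` belong to the pathway. Computed through SciPy's log-gamma
    based survival function for numerical stability.
    """
    k, big_k, n, big_n = int(k), int(big_k), int(n), int(big_n)
    if not (0 <= big_k <= big_n and 0 <= n <= big_n):
        raise ValidationError(f"inconsistent counts K={big_k}, n={n}, N={big_n}")
    if not 0 <= k <= min(big_k, n):
        raise ValidationError(f"k={k} outside [0, min(K={big_k}, n={n})]")
    return float(stats.hypergeom.sf(k - 1, big_n, big_k, n))


def enrich(
    differential: pd.DataFrame,
    annotation: pd.DataFrame,
    background: list[str],
) -> pd.DataFrame:
    """Over-representation of the differential set in each pathway.

    Parameters
    ----------
    differential:
        Screen output with columns ``compound`` and ``status`` (rows with
        status ``up`` or ``down`` form the differential set; a compound
        differential in several comparisons counts once, with direction
        counts over its unique statuses).
    annotation:
        Long map with columns ``pathway_id``, ``compound`` and optionally
        ``pathway_name``. Members outside the background are ignored;
        pathways with no background member are skipped.
    background:
        The compound universe (all compounds detected in the experiment).

    Returns
    -------
    pandas.DataFrame
        One row per pathway, sorted by p ascending then pathway id:
        ``pathway_id, pathway_name, k, K, n, N, p, fdr, up, down``.
    """
    background_set = set(background)
    if not background_set:
        raise ValidationError("background universe is empty")
    sig = differential[differential["status"].isin(["up", "down"])]
    diff_set = set(sig["compound"])
    outside = diff_set - background_set
    if outside:
        raise ValidationError(f"differential compounds missing from background: {sorted(outside)[:5]}")
    direction = sig.groupby("compound")["status"].agg(set)

    rows = []
    for pid, members_df in annotation.groupby("pathway_id"):
        members = set(members_df["compound"]) & background_set
        if not members:
            continue  # pathway has no detected member; nothing to test
        hits = members & diff_set
        name = members_df["pathway_name"].iloc[0] if "pathway_name" in members_df.columns else ""
        rows.append(
            {
                "pathway_id": pid,
                "pathway_name": name,
                "k": len(hits),
                "K": len(members),
                "n": len(diff_set),
                "N": len(background_set),
                "p": hypergeom_upper(len(hits), len(members), len(diff_set), len(background_set)),
                "up": sum("up" in direction[c] for c in hits),
                "down": sum("down" in direction[c] for c in hits),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["pathway_id", "pathway_name", "k", "K", "n", "N", "p", "fdr", "up", "down"]
        )
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    out = out.sort_values(["p", "pathway_id"], kind="stable").reset_index(drop=True)
    return out[["pathway_id", "pathway_name", "k", "K", "n", "N", "p", "fdr", "up", "down"]]


def pathway_trend_report(
    voc: pd.DataFrame, annotation: pd.DataFrame, pathway_id: str
) -> pd.DataFrame:
    """Stage profiles of one pathway's compounds, per cultivar.

    For every (cultivar, member compound) present in the survey the
    report gives the standardized four-stage profile, the stage of
    maximum content (1 flower-bud .. 4 withering) and a ``no_trend`` flag
    for constant profiles.
    """
    members = annotation.loc[annotation["pathway_id"] == pathway_id, "compound"]
    if members.empty:
        raise ValidationError(f"unknown pathway {pathway_id!r}")
    sub = voc[voc["compound"].isin(set(members))]
    if sub.empty:
        return pd.DataFrame(
            columns=["cultivar", "compound", "stage_1", "stage_2", "stage_3", "stage_4", "stage_of_max", "no_trend"]
        )
    rows = []
    for (cultivar, compound), grp in sub.groupby(["cultivar", "compound"]):
        prof = grp.groupby("stage")["concentration"].mean()
        prof = prof.reindex([1, 2, 3, 4])
        x = prof.to_numpy(dtype=float)
        sd = np.nanstd(x)
        z = (x - np.nanmean(x)) / sd if sd > 0 else np.zeros_like(x)
        rows.append(
            {
                "cultivar": cultivar,
                "compound": compound,
                **{f"stage_{s}": z[s - 1] for s in range(1, 5)},
                "stage_of_max": int(np.nanargmax(x)) + 1,
                "no_trend": bool(sd == 0),
            }
        )
    return pd.DataFrame(rows).sort_values(["cultivar", "compound"]).reset_index(drop=True)
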
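"""Genus-level rank-abundance profiles colored by plurality novelty bin.

Genera are labelled "phylum_lowest-identified-group" from the taxonomy
string, ranked by abundance (sequence count or summed read depth) within
each environment, and each genus is assigned the novelty bin holding the
most of its sequences. Observations whose taxonomy resolves no rank below
the phylum form their own "unclassified" group per phylum rather than
being dropped — uncultured bins may lump many true genera, and dropping
them would hide exactly the novel taxa of interest.
"""

from __future__ import annotations

import pandas as pd

from .classify import BIN_LABELS, NoveltyBin
from .errors import DataError, ParameterError

RANK_COLUMNS = ["environment", "rank", "genus_label", "abundance",
                "plurality_bin", "domain"]


def genus_label_from_taxonomy(taxonomy) -> str:
    """Format a 7-rank taxonomy as ``phylum_lowest identified group``."""
    if not isinstance(taxonomy, str) or not taxonomy.strip():
        return "unclassified_unclassified"
    ranks = [r.strip() for r in taxonomy.split(";")]
    phylum = ranks[1] if len(ranks) > 1 and ranks[1] and ranks[1] != "unclassified" \
        else "unclassified"
    lowest = "unclassified"
    for r in reversed(ranks[1:]):
        if r and r != "unclassified":
            lowest = r
            break
    return f"{phylum}_{lowest}"


def plurality_bin(bins) -> str:
    """Bin with the most observations; ties go to the more novel bin."""
    counts = pd.Series(list(bins)).value_counts()
    if counts.empty:
        raise ParameterError("plurality_bin needs at least one observation")
    best = counts.max()
    tied = [b for b in counts.index if counts[b] == best]
    # NoveltyBin is ordered least -> most novel; pick the largest value
    return max(tied, key=lambda label: NoveltyBin.from_label(label).value)


def genus_abundances(observations: pd.DataFrame,
                     abundance_mode: str = "count") -> pd.DataFrame:
    """Ranked genus abundances per environment.

    ``abundance_mode`` is ``"count"`` or ``"depth"`` (summed read depth).
    Ranks are 1..n within each environment, descending abundance, ties
    broken by genus label. A ``genus_label`` column is derived from
    ``taxonomy`` when absent.
    """
    if abundance_mode not in ("count", "depth"):
        raise ParameterError(f"unknown abundance_mode {abundance_mode!r}")
    obs = observations.copy()
    if "genus_label" not in obs.columns:
        if "taxonomy" not in obs.columns:
            raise DataError("observations need genus_label or taxonomy")
        obs["genus_label"] = obs["taxonomy"].map(genus_label_from_taxonomy)
    bad = set(obs["bin"]) - set(BIN_LABELS)
    if bad:
        raise DataError(f"unknown bin labels: {sorted(bad)}")
    if abundance_mode == "depth" and "read_depth" not in obs.columns:
        raise DataError("depth mode needs a read_depth column")
    rows = []
    for env, group in obs.groupby("environment", sort=True):
        agg = []
        for label, genus in group.groupby("genus_label", sort=True):
            abundance = float(genus["read_depth"].sum()) if abundance_mode == "depth" \
                else float(len(genus))
            domain = genus["domain"].mode().iloc[0] if "domain" in genus else ""
            agg.append((label, abundance, plurality_bin(genus["bin"]), domain))
        agg.sort(key=lambda t: (-t[1], t[0]))
        for rank, (label, abundance, pbin, domain) in enumerate(agg, start=1):
            rows.append((env, rank, label, abundance, pbin, domain))
    return pd.DataFrame(rows, columns=RANK_COLUMNS)


def top_n(ranked: pd.DataFrame, n: int = 10) -> pd.DataFrame:
    """First ``n`` ranks per environment (fewer when a group is smaller)."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    return (ranked[ranked["rank"] <= n]
            .sort_values(["environment", "rank"])
            .reset_index(drop=True))


def plot_rank_abundance(ranked: pd.DataFrame, path) -> None:
    """Rank-abundance scatter per environment, colored by plurality bin.

    Requires matplotlib (optional dependency).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {BIN_LABELS[0]: "tan", BIN_LABELS[1]: "palevioletred",
              BIN_LABELS[2]: "teal"}
    envs = ranked["environment"].unique()
    fig, axes = plt.subplots(1, len(envs), figsize=(4 * len(envs), 3.2),
                             squeeze=False)
    for ax, env in zip(axes[0], envs):
        sub = ranked[ranked["environment"] == env]
        for label in BIN_LABELS:
            sel = sub[sub["plurality_bin"] == label]
            ax.scatter(sel["rank"], sel["abundance"], s=12,
                       color=colors[label], label=label)
        ax.set_yscale("log")
        ax.set_title(env)
        ax.set_xlabel("genus rank")
    axes[0][0].set_ylabel("abundance")
    axes[0][-1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
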
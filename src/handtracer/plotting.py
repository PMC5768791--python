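"""Optional figures: per-family stacked decomposition of palm attributions."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .attribution_stats import AttributionSummary, RELATIONS
from .io_tables import SampleMetadata

SITE_COLORS = {"forehead": "#c9b458", "stool": "#8c5a3c",
               "tongue": "#c94f4f", "unknown": "#9aa0a6"}


def plot_family_decomposition(summaries: list[AttributionSummary],
                              metadata: SampleMetadata, family_id: str,
                              ax=None):
    """Stacked bars of site x relation attribution for one family's palms.

    Each palm is a bar; colour encodes the source body site, hatching the
    relation of the source's host to the palm owner (self plain, family
    hatched, unrelated dotted, unknown grey).
    """
    fam = [s for s in summaries
           if metadata.family_of(s.palm_id) == family_id]
    if not fam:
        raise ValueError(f"no palms for family {family_id!r}")
    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * len(fam) + 2, 4))
    hatches = {"self": "", "family": "//", "unrelated": ".."}
    for i, s in enumerate(fam):
        bottom = 0.0
        for site in ("forehead", "stool", "tongue"):
            for rel in RELATIONS:
                v = s.by_site_relation[(site, rel)]
                if v > 1e-6:
                    ax.bar(i, v, bottom=bottom, color=SITE_COLORS[site],
                           hatch=hatches[rel], edgecolor="white", width=0.8)
                    bottom += v
        ax.bar(i, s.by_site["unknown"], bottom=bottom,
               color=SITE_COLORS["unknown"], width=0.8)
    ax.set_xticks(np.arange(len(fam)))
    ax.set_xticklabels([s.palm_id for s in fam], rotation=45, ha="right")
    ax.set_ylabel("attributed proportion")
    ax.set_ylim(0, 1)
    ax.set_title(f"family {family_id}: palm source decomposition")
    return ax
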
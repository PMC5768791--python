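import numpy as np
import pandas as pd
import pytest

import handtracer as ht
from handtracer.io_tables import SampleMetadata
from handtracer.st_core import GibbsParams, fit_all


@pytest.fixture(scope="session")
def cohort3():
    """Small default-preset cohort: 3 families x 3 members."""
    return ht.generate_population(ht.default_spec(n_families=3, seed=5))


@pytest.fixture(scope="session")
def fitted3(cohort3):
    """Baseline attribution of the small cohort (reduced chain schedule)."""
    params = GibbsParams(restarts=5, burnin=50, seed=9)
    return fit_all(cohort3.table, cohort3.metadata, params, sink_depth=800)


def make_metadata(rows):
    """Metadata from (sample_id, host, family, site[, extras]) tuples."""
    recs = []
    for r in rows:
        rec = {"sample_id": r[0], "host_id": r[1], "family_id": r[2],
               "body_site": r[3]}
        if len(r) > 4:
            rec.update(r[4])
        recs.append(rec)
    return SampleMetadata(pd.DataFrame(recs).set_index("sample_id"))


@pytest.fixture
def family_metadata():
    """One palm owner plus sources spanning sites and relations."""
    return make_metadata([
        ("kid.palm.left", "kid", "famA", "palm", {"hand_side": "left"}),
        ("kid.forehead", "kid", "famA", "forehead"),
        ("kid.stool", "kid", "famA", "stool"),
        ("kid.tongue", "kid", "famA", "tongue"),
        ("mom.stool", "mom", "famA", "stool"),
        ("mom.tongue", "mom", "famA", "tongue"),
        ("stranger.stool", "stranger", "famB", "stool"),
        ("stranger.forehead", "stranger", "famB", "forehead"),
    ])
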
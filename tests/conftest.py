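from __future__ import annotations

from datetime import datetime, timezone

import numpy as np
import pandas as pd
import pytest

from kratkit import ephemeris, features, synth


@pytest.fixture(scope="session")
def site() -> ephemeris.SiteContext:
    """Representative Chihuahuan-desert test site (30.2 N, 103.5 W)."""
    return ephemeris.SiteContext(30.2, -103.5, "America/Chicago")


@pytest.fixture(scope="session")
def deployment(site):
    """One 14 h synthetic deployment spanning an evening-to-morning night."""
    return synth.simulate_deployment(
        "kr00", datetime(2021, 6, 1, 18, tzinfo=timezone.utc), 14.0, site, seed=1234
    )


@pytest.fixture(scope="session")
def labeled_table(deployment):
    """6 s labeled feature table for the session deployment."""
    ann = synth.schedule_to_annotations("kr00", deployment.schedule)
    return features.feature_table(deployment.trace, 6.0, annotations=ann)


@pytest.fixture(scope="session")
def training_tables(site):
    """Labeled feature tables (2 s and 6 s) pooled over three deployments.

    Sized so every behavior class has well over 300 windows at 6 s before
    balancing.
    """
    deps = [
        synth.simulate_deployment(
            f"kr{i:02d}",
            datetime(2021, 6, 1 + i, 18, tzinfo=timezone.utc),
            14.0,
            site,
            seed=100 + i,
        )
        for i in range(3)
    ]
    tables = {}
    for w in (2.0, 6.0):
        parts = []
        for d in deps:
            ann = synth.schedule_to_annotations(d.individual_id, d.schedule)
            parts.append(features.feature_table(d.trace, w, annotations=ann))
        tables[w] = pd.concat(parts, ignore_index=True)
    return tables
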
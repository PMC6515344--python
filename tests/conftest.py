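import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def small_metadata():
    """Four cases + four controls with MRC/MIRS covariates."""
    return pd.DataFrame(
        {
            "sample_id": [f"case_{i}" for i in range(1, 5)] + [f"ctrl_{i}" for i in range(1, 5)],
            "group": ["case"] * 4 + ["control"] * 4,
            "mrc_megascore": [110.0, 115.0, 120.0, 125.0, 130.0, 130.0, 130.0, 130.0],
            "mirs_stage": [5, 4, 3, 2, np.nan, np.nan, np.nan, np.nan],
            "lib_size": [10_000_000] * 8,
        }
    )


def random_ratio_fixture(rng, max_events=20, max_samples=10):
    """A random back-splice + linear-junction fixture for oracle tests.

    Events sit on a couple of chromosomes with occasional shared
    donor/acceptor sites; linear junctions are generated so that some
    match an event's sites, some don't, and zeros occur.
    """
    from circlin.io import JunctionCountTable, event_id_for

    n_events = int(rng.integers(1, max_events + 1))
    n_samples = int(rng.integers(2, max_samples + 1))
    samples = [f"s{i}" for i in range(n_samples)]
    rows = []
    seen = set()
    for _ in range(n_events):
        chrom = f"chr{rng.integers(1, 3)}"
        start = int(rng.integers(1, 20)) * 100
        end = start + int(rng.integers(1, 10)) * 100
        strand = rng.choice(["+", "-", "."])
        key = (chrom, start, end)
        if key in seen:
            continue
        seen.add(key)
        rows.append(
            {"event_id": event_id_for(chrom, start, end), "chrom": chrom,
             "start": start, "end": end, "strand": strand, "gene_id": f"G{len(rows)}"}
        )
    events = pd.DataFrame(rows).set_index("event_id")
    counts = pd.DataFrame(
        rng.integers(0, 30, size=(len(events), n_samples)).astype(float),
        index=events.index, columns=samples,
    )
    table = JunctionCountTable(
        events=events, counts=counts, normalized=False,
        lib_sizes=pd.Series(1_000_000, index=samples),
    )

    lin_rows = []
    for _, ev in events.iterrows():
        for anchor in (ev["start"], ev["end"]):
            for _ in range(int(rng.integers(0, 3))):
                other = int(anchor + rng.choice([-1, 1]) * int(rng.integers(1, 5)) * 50)
                if other == anchor:
                    continue
                donor, acceptor = (anchor, other) if rng.random() < 0.5 else (other, anchor)
                for s in samples:
                    lin_rows.append(
                        {"chrom": ev["chrom"], "donor_pos": donor, "acceptor_pos": acceptor,
                         "strand": rng.choice(["+", "-", "."]), "sample_id": s,
                         "count": float(rng.integers(0, 40))}
                    )
    linear = pd.DataFrame(
        lin_rows,
        columns=["chrom", "donor_pos", "acceptor_pos", "strand", "sample_id", "count"],
    )
    meta = pd.DataFrame(
        {"sample_id": samples,
         "group": ["case" if i % 2 else "control" for i in range(n_samples)]}
    )
    return table, linear, meta
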
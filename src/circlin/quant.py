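"""RNA-seq arm: normalization, presence filtering and circular-to-linear ratios.

The central statistic is the per-sample circular-to-linear ratio of a
back-splice event: its junction-read count divided by the read count of
the most abundant linear splice junction sharing the event's donor or
acceptor site in the same sample. Using the best linear partner keeps
the comparison between two reads-per-junction quantities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from circlin.io import BackspliceEvent, JunctionCountTable

logger = logging.getLogger(__name__)

# ratio cell status codes
OK = "ok"
ZERO_CIRC = "zero_circ"
NO_LINEAR_PARTNER = "no_linear_partner"
BOTH_ZERO = "both_zero"


@dataclass
class RatioMatrix:
    """Events x samples circular-to-linear ratios with per-cell status.

    ``values`` holds the ratio where status is ``ok`` or ``zero_circ``
    and NaN where no linear partner exists (``no_linear_partner`` =
    circular-only expression, ``both_zero`` = nothing detected).
    ``summaries`` carries per-event group means/medians over defined
    cells plus the fraction of cells with status ``ok``.
    """

    values: pd.DataFrame
    status: pd.DataFrame
    summaries: pd.DataFrame


def normalize_per_million(table: JunctionCountTable) -> JunctionCountTable:
    """Scale raw junction counts to reads-per-million of library size."""
    if table.normalized:
        raise ValueError("table is already normalized")
    sizes = table.lib_sizes.reindex(table.samples)
    if (sizes <= 0).any():
        raise ValueError("zero or negative library size")
    counts = table.counts * (1e6 / sizes)
    return JunctionCountTable(
        events=table.events, counts=counts, normalized=True, lib_sizes=table.lib_sizes
    )


def normalize_linear_per_million(linear: pd.DataFrame, lib_sizes: pd.Series) -> pd.DataFrame:
    """Per-million normalization of a linear-junction table.

    The circular-to-linear ratio requires the back-splice count and
    the linear counts on one scale, so whatever normalization the
    back-splice table received must be applied here too.
    """
    sizes = linear["sample_id"].map(pd.Series(lib_sizes))
    if sizes.isna().any():
        missing = sorted(set(linear.loc[sizes.isna(), "sample_id"]))
        raise ValueError(f"lib_sizes missing for samples: {missing}")
    if (sizes <= 0).any():
        raise ValueError("zero or negative library size")
    out = linear.copy()
    out["count"] = out["count"] * (1e6 / sizes)
    return out


def presence_filter(
    table: JunctionCountTable,
    metadata: pd.DataFrame,
    min_fraction: float = 0.7,
    mode: str = "either",
) -> JunctionCountTable:
    """Keep events detected in enough samples of the study groups.

    Presence means raw count > 0 (detection, not an abundance level).
    With ``mode="either"`` an event survives when its presence fraction
    reaches ``min_fraction`` in the control group OR in the case group;
    ``mode="both"`` requires both groups. Event order is preserved.
    """
    if mode not in ("either", "both"):
        raise ValueError(f"unknown presence mode {mode!r}")
    meta = metadata.set_index("sample_id")["group"].reindex(table.samples)
    present = table.counts > 0
    fracs = {}
    for grp in ("control", "case"):
        cols = [s for s in table.samples if meta.get(s) == grp]
        if not cols:
            raise ValueError(f"presence_filter: group {grp!r} has zero samples")
        fracs[grp] = present[cols].mean(axis=1)
    if mode == "either":
        keep = (fracs["control"] >= min_fraction) | (fracs["case"] >= min_fraction)
    else:
        keep = (fracs["control"] >= min_fraction) & (fracs["case"] >= min_fraction)
    logger.info(
        "presence_filter(min_fraction=%.2f, mode=%s): kept %d/%d events",
        min_fraction, mode, int(keep.sum()), len(keep),
    )
    return JunctionCountTable(
        events=table.events[keep],
        counts=table.counts[keep],
        normalized=table.normalized,
        lib_sizes=table.lib_sizes,
    )


def _strand_compatible(a: str, b: str) -> bool:
    return a == "." or b == "." or a == b


def _candidate_mask(event: BackspliceEvent, linear: pd.DataFrame) -> pd.Series:
    """Linear junctions sharing the event's donor or acceptor site.

    A junction qualifies when, on the same chromosome and a compatible
    strand, its donor position equals the event's donor coordinate or
    its acceptor position equals the event's acceptor coordinate. For
    an unstranded event the donor/acceptor role assignment is unknown,
    so both orientations are accepted.
    """
    same_chrom = linear["chrom"] == event.chrom
    strand_ok = linear["strand"].map(lambda s: _strand_compatible(event.strand, s))
    donor, acceptor = event.donor_acceptor()
    hit = (linear["donor_pos"] == donor) | (linear["acceptor_pos"] == acceptor)
    if event.strand == ".":
        hit |= (linear["donor_pos"] == acceptor) | (linear["acceptor_pos"] == donor)
    return same_chrom & strand_ok & hit


def circ_lin_ratio(
    event: BackspliceEvent,
    bs_count: float,
    linear: pd.DataFrame,
    sample_id: str,
) -> tuple[float, str, tuple[int, int] | None]:
    """Circular-to-linear ratio of one event in one sample.

    Returns ``(ratio, status, partner)`` where ``partner`` is the
    (donor_pos, acceptor_pos) of the winning linear junction, or None
    when no candidate exists. The back-splice count and the linear
    counts must be on the same normalization scale. Division by zero is
    never emitted: a back-splice with no expressed linear partner is
    reported as circular-only (``no_linear_partner``) instead of an
    infinite ratio.

    Ties on the maximal linear count leave the ratio unchanged; the
    reported partner is the tied junction with the smallest donor
    position, then smallest acceptor position.
    """
    sub = linear[(linear["sample_id"] == sample_id) & _candidate_mask(event, linear)]
    sub = sub[sub["count"] > 0]
    if sub.empty:
        if bs_count > 0:
            return np.nan, NO_LINEAR_PARTNER, None
        return np.nan, BOTH_ZERO, None
    max_count = sub["count"].max()
    winners = sub[sub["count"] == max_count].sort_values(["donor_pos", "acceptor_pos"])
    partner = (int(winners.iloc[0]["donor_pos"]), int(winners.iloc[0]["acceptor_pos"]))
    if bs_count == 0:
        return 0.0, ZERO_CIRC, partner
    return float(bs_count) / float(max_count), OK, partner


def ratio_matrix(
    table: JunctionCountTable,
    linear: pd.DataFrame,
    metadata: pd.DataFrame,
) -> RatioMatrix:
    """Apply `circ_lin_ratio` to every (event, sample) cell.

    Group summaries (mean and median ratio per group) ignore cells with
    no defined ratio; ``frac_ok`` is the fraction of samples in which
    both the back-splice and a linear partner were observed.
    """
    samples = table.samples
    values = pd.DataFrame(np.nan, index=table.events.index, columns=samples)
    status = pd.DataFrame(BOTH_ZERO, index=table.events.index, columns=samples)

    for event_id, row in table.events.iterrows():
        event = BackspliceEvent(
            chrom=row["chrom"], start=int(row["start"]), end=int(row["end"]),
            strand=row["strand"], gene_id=row["gene_id"],
        )
        # restrict once per event; the per-sample filter happens inside
        cand = linear[_candidate_mask(event, linear)]
        for sid in samples:
            ratio, stat, _ = circ_lin_ratio(event, table.counts.at[event_id, sid], cand, sid)
            values.at[event_id, sid] = ratio
            status.at[event_id, sid] = stat

    groups = metadata.set_index("sample_id")["group"]
    case_cols = [s for s in samples if groups.get(s) == "case"]
    ctrl_cols = [s for s in samples if groups.get(s) == "control"]
    summaries = pd.DataFrame(
        {
            "mean_case": values[case_cols].mean(axis=1),
            "mean_control": values[ctrl_cols].mean(axis=1),
            "median_case": values[case_cols].median(axis=1),
            "median_control": values[ctrl_cols].median(axis=1),
            "frac_ok": (status == OK).mean(axis=1),
        }
    )
    return RatioMatrix(values=values, status=status, summaries=summaries)


def intersect_candidates(
    events: pd.DataFrame,
    candidate_ids: set[str],
) -> tuple[pd.DataFrame, pd.Series]:
    """Restrict an event table to a candidate list.

    Candidates may be event ids (``chrom:start|end``) or gene ids; a
    gene-level candidate returns every back-splice isoform of that gene
    (distinct circRNAs from one gene are tracked separately downstream).
    Returns the subset plus, per kept event, which key matched.
    Candidate ids matching nothing are ignored with a log line.
    """
    by_event = events.index.to_series().isin(candidate_ids)
    by_gene = events["gene_id"].isin(candidate_ids)
    keep = by_event | by_gene
    match_key = pd.Series("", index=events.index, dtype=object)
    match_key[by_gene] = "gene_id"
    match_key[by_event] = "event_id"  # event-level match wins when both apply
    used = set(events.index[by_event]) | set(events.loc[by_gene, "gene_id"])
    unused = candidate_ids - used
    if unused:
        logger.info("intersect_candidates: %d candidate id(s) not found: %s",
                    len(unused), sorted(unused))
    return events[keep], match_key[keep]
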
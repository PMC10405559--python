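"""Reconciliation of multi-engine peptide identifications per cluster.

Each spectrum (replicate or consensus) may carry identifications from up to
three engines — database search, open-modification search and de novo
sequencing.  Per spectrum, one sequence is chosen by engine priority
(database > open_mod > de_novo, using only engine-accepted records).  Per
cluster, the member sequences plus the consensus spectrum's own sequence
vote; the plurality wins, with the consensus spectrum's sequence breaking
ties.  The scheme rescues members whose own database search failed and
corrects members whose database hit disagrees with the cluster majority.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .clustering import SpectrumCluster

logger = logging.getLogger("metaspectra")

METHODS = ("database", "open_mod", "de_novo")
_METHOD_PRIORITY = {m: i for i, m in enumerate(METHODS)}


@dataclass(frozen=True)
class IdentificationRecord:
    spectrum_id: str
    method: str
    peptide: str
    score: float
    passes: bool

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown identification method {self.method!r}")
        if self.passes and not self.peptide:
            raise ValueError("a passing record must carry a peptide sequence")


@dataclass
class ConsensusPeptide:
    cluster_id: str
    sequence: str | None
    winning_method: str | None
    votes: dict[str, int]
    tie_broken: bool = False
    rescued: bool = False
    corrected_member_ids: list[str] = field(default_factory=list)


def canonical_peptide(peptide: str, equate_il: bool = False) -> str:
    """Normalize a peptide string for exact comparison.

    Modification masses in brackets are rounded to 2 decimals so engines
    printing different precisions agree; I/L are equated only on request.
    """
    def _round_mod(match: re.Match) -> str:
        return f"[{float(match.group(1)):+.2f}]"

    out = re.sub(r"\[([+-]?\d+(?:\.\d+)?)\]", _round_mod, peptide.strip())
    if equate_il:
        out = re.sub(r"[IL]", "J", out)
    return out


# ---------------------------------------------------------------------------
# Identification tables
# ---------------------------------------------------------------------------

def read_id_table(path: str | Path) -> list[IdentificationRecord]:
    """Read per-spectrum engine results from TSV.

    Columns: spectrum_id, method, peptide, score, passes.  Failing rows are
    retained but never vote; a passing row without a peptide is rejected
    with a warning; duplicate (spectrum_id, method) keeps the last row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"spectrum_id", "method", "peptide", "score", "passes"}
    if not required <= set(df.columns):
        raise ValueError(f"identification table must have columns {sorted(required)}")
    records: dict[tuple[str, str], IdentificationRecord] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        method = row.method.strip()
        if method not in METHODS:
            raise ValueError(
                f"{path}: row {row_no}: unknown method {method!r} "
                f"(expected one of {METHODS})"
            )
        passes = row.passes.strip().lower() in ("1", "true", "yes")
        peptide = row.peptide.strip()
        if passes and not peptide:
            logger.warning("%s: row %d passes but has no peptide; rejected", path, row_no)
            continue
        key = (row.spectrum_id, method)
        if key in records:
            logger.warning(
                "%s: duplicate record for spectrum %r method %r; last wins",
                path, row.spectrum_id, method,
            )
        records[key] = IdentificationRecord(
            spectrum_id=row.spectrum_id,
            method=method,
            peptide=peptide,
            score=float(row.score) if row.score else 0.0,
            passes=passes,
        )
    return list(records.values())


def spectrum_sequence(
    records: list[IdentificationRecord], equate_il: bool = False
) -> tuple[str, str] | None:
    """Pick one (sequence, method) for a spectrum by engine priority.

    Database search wins whenever it passes; otherwise open-modification
    search; de novo only when both fail.  None when nothing passes.
    """
    passing = [r for r in records if r.passes]
    if not passing:
        return None
    best = min(passing, key=lambda r: _METHOD_PRIORITY[r.method])
    return canonical_peptide(best.peptide, equate_il), best.method


# ---------------------------------------------------------------------------
# Voting
# ---------------------------------------------------------------------------

def vote(
    cluster_id: str,
    member_sequences: list[tuple[str, str] | None],
    consensus_sequence: tuple[str, str] | None,
) -> ConsensusPeptide:
    """Plurality vote over member sequences plus the consensus spectrum's.

    Unidentified spectra abstain.  The consensus spectrum casts a full
    ballot and additionally breaks ties: a tied sequence equal to the
    consensus spectrum's wins.  Residual ties fall to the method priority of
    each sequence's best supporting ballot, then lexicographic order.
    """
    ballots = [s for s in member_sequences if s is not None]
    if consensus_sequence is not None:
        ballots.append(consensus_sequence)
    if not ballots:
        return ConsensusPeptide(cluster_id, None, None, votes={})

    tally: dict[str, int] = {}
    best_method: dict[str, int] = {}
    for seq, method in ballots:
        tally[seq] = tally.get(seq, 0) + 1
        prio = _METHOD_PRIORITY[method]
        best_method[seq] = min(best_method.get(seq, prio), prio)

    top = max(tally.values())
    tied = sorted(s for s, c in tally.items() if c == top)
    tie_broken = False
    if len(tied) == 1:
        winner = tied[0]
    elif consensus_sequence is not None and consensus_sequence[0] in tied:
        winner = consensus_sequence[0]
        tie_broken = True
    else:
        winner = min(tied, key=lambda s: (best_method[s], s))
        tie_broken = True

    method = METHODS[best_method[winner]]
    return ConsensusPeptide(
        cluster_id, winner, method, votes=tally, tie_broken=tie_broken
    )


def reconcile_all(
    clusters: list[SpectrumCluster],
    records: list[IdentificationRecord],
    equate_il: bool = False,
) -> tuple[list[ConsensusPeptide], dict[str, int]]:
    """Vote every cluster; tally rescued and corrected members.

    A member is *rescued* when it has no passing database hit of its own but
    its cluster's consensus spectrum does.  A member is *corrected* when its
    own passing database sequence differs from the final consensus peptide.
    Records whose spectrum_id matches neither a member nor a cluster_id are
    ignored with a warning.
    """
    by_spectrum: dict[str, list[IdentificationRecord]] = {}
    for r in records:
        by_spectrum.setdefault(r.spectrum_id, []).append(r)
    known = {sid for c in clusters for sid in c.member_ids} | {
        c.cluster_id for c in clusters
    }
    orphans = set(by_spectrum) - known
    if orphans:
        logger.warning("%d identification record id(s) match no spectrum or cluster", len(orphans))

    results: list[ConsensusPeptide] = []
    n_rescued = 0
    n_corrected = 0
    for c in clusters:
        member_recs = {sid: by_spectrum.get(sid, []) for sid in c.member_ids}
        member_seqs = [
            spectrum_sequence(member_recs[sid], equate_il) for sid in c.member_ids
        ]
        cons_seq = spectrum_sequence(by_spectrum.get(c.cluster_id, []), equate_il)
        cp = vote(c.cluster_id, member_seqs, cons_seq)

        cons_has_db = any(
            r.passes and r.method == "database" for r in by_spectrum.get(c.cluster_id, [])
        )
        for sid in c.member_ids:
            own_db = [
                r for r in member_recs[sid] if r.passes and r.method == "database"
            ]
            if not own_db:
                if cons_has_db:
                    n_rescued += 1
                    cp.rescued = True
            elif cp.sequence is not None:
                own_seq = canonical_peptide(own_db[-1].peptide, equate_il)
                if own_seq != cp.sequence:
                    n_corrected += 1
                    cp.corrected_member_ids.append(sid)
        results.append(cp)

    n_identified = sum(1 for cp in results if cp.sequence is not None)
    summary = {
        "n_clusters": len(clusters),
        "n_identified": n_identified,
        "n_unidentified": len(clusters) - n_identified,
        "rescued_members": n_rescued,
        "corrected_members": n_corrected,
    }
    return results, summary


def filter_host_clusters(
    clusters: list[SpectrumCluster], exclusion_ids: list[str] | set[str]
) -> list[SpectrumCluster]:
    """Drop clusters whose consensus matched a host (e.g. mouse) protein.

    The exclusion list typically comes from searching the consensus spectra
    against the host proteome with an external engine.
    """
    excl = set(exclusion_ids)
    unknown = excl - {c.cluster_id for c in clusters}
    if unknown:
        logger.warning("%d exclusion id(s) match no cluster", len(unknown))
    return [c for c in clusters if c.cluster_id not in excl]


def write_reconciliation(
    results: list[ConsensusPeptide], summary: dict[str, int], out_tsv, out_json=None
) -> None:
    rows = [
        {
            "cluster_id": cp.cluster_id,
            "sequence": cp.sequence or "",
            "winning_method": cp.winning_method or "",
            "votes": ";".join(f"{s}:{c}" for s, c in sorted(cp.votes.items())),
            "tie_broken": cp.tie_broken,
            "rescued": cp.rescued,
            "n_corrected": len(cp.corrected_member_ids),
        }
        for cp in results
    ]
    pd.DataFrame(rows).to_csv(out_tsv, sep="\t", index=False)
    if out_json is not None:
        Path(out_json).write_text(json.dumps(summary, indent=2))
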
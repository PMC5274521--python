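"""Benchmark scoring: sensitivity, specificity and TSD recall.

A call is a true positive when its position (interval midpoint) lies
within ``tolerance_bp`` (default 100) of a planted insertion point on the
same chromosome; each call is charged to its nearest truth record.
Sensitivity is the fraction of planted insertions recalled by at least
one call; specificity the fraction of calls that are true positives; TSD
recall the fraction of true-positive calls whose TSD string equals the
simulated duplicated motif.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .genome_mapper import GenomeIndex
from .insertion_caller import CandidateInsertion, run_pipeline
from .io_formats import ReferenceGenome, RunConfig, TELibrary
from .repeat_matcher import LibraryIndex
from .simulator import ReadSimParams, SimulatedTruth, plant_insertions, simulate_reads

__all__ = ["EvalResult", "evaluate", "benchmark_sweep", "summarize_sweep"]


@dataclass(frozen=True)
class EvalResult:
    n_truth: int
    n_calls: int
    n_true_positive_calls: int
    n_recalled_truth: int
    sensitivity: Optional[float]   # None when there is no truth
    specificity: Optional[float]   # None when there are no calls
    tsd_recall: Optional[float]    # None when there are no TP calls


def _call_pos(c: CandidateInsertion) -> float:
    # midpoint of the (0-based half-open) interval, as an inclusive midpoint
    return (c.start + c.end - 1) / 2.0


def evaluate(calls: Sequence[CandidateInsertion],
             truth: Sequence[SimulatedTruth],
             tolerance_bp: int = 100) -> EvalResult:
    """Score calls against planted truth under the positional tolerance."""
    call_chroms = {c.chrom for c in calls}
    truth_chroms = {t.chrom for t in truth}
    if calls and truth and not (call_chroms & truth_chroms):
        raise ValueError(
            f"calls ({sorted(call_chroms)}) and truth ({sorted(truth_chroms)}) "
            "share no chromosome — different references?")

    by_chrom: Dict[str, List[SimulatedTruth]] = {}
    for t in truth:
        by_chrom.setdefault(t.chrom, []).append(t)
    for lst in by_chrom.values():
        lst.sort(key=lambda t: t.pos)

    recalled: set = set()
    n_tp = 0
    n_tsd_ok = 0
    for c in calls:
        cands = by_chrom.get(c.chrom)
        if not cands:
            continue
        pos = _call_pos(c)
        positions = [t.pos for t in cands]
        i = int(np.searchsorted(positions, pos))
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(cands):
                d = abs(cands[j].pos - pos)
                # nearest truth; ties -> lower coordinate (the earlier j)
                if best is None or d < best[0]:
                    best = (d, j)
        if best is None or best[0] > tolerance_bp:
            continue
        n_tp += 1
        t = cands[best[1]]
        recalled.add((t.chrom, t.pos))
        if (c.tsd_seq or "") == t.tsd_seq:
            n_tsd_ok += 1

    n_truth = len(truth)
    n_calls = len(calls)
    return EvalResult(
        n_truth=n_truth, n_calls=n_calls,
        n_true_positive_calls=n_tp, n_recalled_truth=len(recalled),
        sensitivity=(len(recalled) / n_truth) if n_truth else None,
        specificity=(n_tp / n_calls) if n_calls else None,
        tsd_recall=(n_tsd_ok / n_tp) if n_tp else None)


def _derive_seed(seed: int, rep: int, tag: int) -> int:
    return (seed * 1_000_003 + rep * 10_007 + tag * 101 + 1) % (2 ** 31)


def benchmark_sweep(ref: ReferenceGenome, library: TELibrary,
                    n_insertions: int, coverages: Sequence[float],
                    replicates: int, seed: int,
                    cfg: Optional[RunConfig] = None,
                    error_rate: float = 0.01) -> pd.DataFrame:
    """Plant -> simulate -> call -> score over a coverage grid.

    One insertion set is planted per replicate (same across coverages,
    mirroring resampling one simulated genome at many depths); reads are
    re-simulated per (replicate, coverage).  Returns a tidy table with one
    row per run.
    """
    cfg = cfg or RunConfig()
    lib_index = LibraryIndex(library, cfg)
    genome_index = GenomeIndex(ref)
    rows = []
    for rep in range(replicates):
        mutated, truth = plant_insertions(
            ref, library, n=n_insertions, seed=_derive_seed(seed, rep, 0),
            min_spacing=2 * cfg.window_bp)
        for cov in coverages:
            params = ReadSimParams(
                coverage=cov, seed=_derive_seed(seed, rep, int(cov * 100)),
                error_rate=error_rate)
            pairs = simulate_reads(mutated, params)
            res = run_pipeline(pairs, library, ref, cfg,
                               lib_index=lib_index, genome_index=genome_index)
            ev = evaluate(res.confident, truth, cfg.match_tolerance_bp)
            rows.append({
                "coverage": cov, "replicate": rep,
                "n_truth": ev.n_truth, "n_calls": ev.n_calls,
                "n_true_positive_calls": ev.n_true_positive_calls,
                "sensitivity": ev.sensitivity,
                "specificity": ev.specificity,
                "tsd_recall": ev.tsd_recall,
            })
    return pd.DataFrame(rows)


def summarize_sweep(table: pd.DataFrame) -> pd.DataFrame:
    """Per-coverage mean and standard deviation across replicates."""
    return (table
            .groupby("coverage")[["sensitivity", "specificity", "tsd_recall"]]
            .agg(["mean", "std"])
            .reset_index())
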
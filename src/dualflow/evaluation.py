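"""Leave-one-out cross-validation, enrichment scoring, and ROC/AUC.

Each known disease gene is held out in turn and re-ranked among a
chromosome-local candidate list of up to 100 genes (the held-out gene plus
its 99 genomically nearest same-chromosome neighbours).  A trial ranked r-th
scores 50/r (the enrichment score); a held-out gene whose protein is absent
from the interaction network is assigned rank 100 and score 0.5.  Two
aggregate enrichment means are reported: score 1 over all trials and
score 2 over on-network trials only.  ROC analysis treats prioritization as
binary classification at a rank threshold, excluding off-network trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network_model import AnnotatedNetwork, GenePartition
from .propagation import PropagationConfig, score_candidates

__all__ = [
    "CandidateList",
    "TrialResult",
    "EvaluationReport",
    "read_positions",
    "read_associations",
    "build_candidate_list",
    "random_candidate_list",
    "loocv",
    "time_split_evaluate",
    "roc_auc",
]

#: default candidate-list size; enrichment is 50/r within this window
CANDIDATE_SIZE = 100


@dataclass(frozen=True)
class CandidateList:
    """A test gene plus its chromosome-local (or sampled) decoy candidates."""

    test_gene: str
    candidates: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.test_gene not in self.candidates:
            raise ValueError("candidate list must include the test gene")


@dataclass(frozen=True)
class TrialResult:
    """Outcome of one held-out gene: its rank and enrichment score."""

    disease: str
    test_gene: str
    rank: int
    enrichment: float
    on_network: bool
    n_candidates: int = CANDIDATE_SIZE


@dataclass(frozen=True)
class EvaluationReport:
    """Per-trial results with per-disease and overall enrichment aggregates.

    ``score1`` averages all trials of a disease; ``score2`` averages only
    trials whose test gene is on the network (NaN when none are).  Overall
    values average per-disease means, treating each disease as one unit.
    """

    trials: tuple[TrialResult, ...]
    mode: str
    per_disease: dict[str, dict[str, float]] = field(default_factory=dict)
    roc_points: tuple[tuple[float, float], ...] = ()
    auc: float = float("nan")

    @property
    def score1(self) -> float:
        vals = [d["score1"] for d in self.per_disease.values()]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def score2(self) -> float:
        vals = [d["score2"] for d in self.per_disease.values() if not np.isnan(d["score2"])]
        return float(np.mean(vals)) if vals else float("nan")

    @classmethod
    def from_trials(cls, trials: list[TrialResult], mode: str) -> "EvaluationReport":
        per: dict[str, dict[str, float]] = {}
        for h in sorted({t.disease for t in trials}):
            mine = [t for t in trials if t.disease == h]
            on = [t for t in mine if t.on_network]
            per[h] = {
                "score1": float(np.mean([t.enrichment for t in mine])),
                "score2": float(np.mean([t.enrichment for t in on])) if on else float("nan"),
                "n_trials": float(len(mine)),
                "n_on_network": float(len(on)),
            }
        points, auc = ((), float("nan"))
        if any(t.on_network for t in trials):
            points, auc = roc_auc(trials)
        return cls(trials=tuple(trials), mode=mode, per_disease=per, roc_points=points, auc=auc)


def read_positions(path) -> pd.DataFrame:
    """Load a gene-position table: TSV columns ``gene chromosome position``."""
    df = pd.read_csv(
        path,
        sep=r"\s+",
        comment="#",
        names=["gene", "chromosome", "position"],
        dtype={"gene": str, "chromosome": str},
    )
    df["position"] = pd.to_numeric(df["position"])
    return df


def read_associations(path) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Load disease-gene associations: TSV ``disease_id gene_id [year]``."""
    df = pd.read_csv(path, sep=r"\s+", comment="#", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("association table needs at least two columns")
    df = df.rename(columns={0: "disease", 1: "gene", 2: "year"})
    if "year" in df.columns:
        df["year"] = pd.to_numeric(df["year"], errors="coerce")
    mapping: dict[str, list[str]] = {}
    for h, sub in df.groupby("disease", sort=True):
        mapping[str(h)] = list(dict.fromkeys(sub["gene"]))
    return mapping, df


def build_candidate_list(
    test_gene: str,
    positions: pd.DataFrame,
    size: int = CANDIDATE_SIZE,
) -> CandidateList:
    """The test gene plus its ``size - 1`` nearest same-chromosome genes.

    Distance is the absolute difference of the per-gene coordinate; ties at
    the inclusion boundary break by identifier order.  Chromosomes with
    fewer than ``size`` genes yield a shorter list.
    """
    rows = positions.loc[positions["gene"] == test_gene]
    if rows.empty:
        raise KeyError(f"test gene {test_gene!r} absent from positions table")
    chrom = rows.iloc[0]["chromosome"]
    pos = float(rows.iloc[0]["position"])
    same = positions.loc[positions["chromosome"] == chrom, ["gene", "position"]].copy()
    same = same.drop_duplicates(subset="gene")
    same["distance"] = (same["position"].astype(float) - pos).abs()
    same = same.sort_values(["distance", "gene"], kind="mergesort")
    chosen = list(same["gene"].head(size))
    if test_gene not in chosen:  # displaced by an identifier tie at distance 0
        chosen = [test_gene] + [g for g in chosen if g != test_gene][: size - 1]
    return CandidateList(test_gene=test_gene, candidates=tuple(chosen))


def random_candidate_list(
    test_gene: str,
    net: AnnotatedNetwork,
    partition: GenePartition,
    rng: np.random.Generator,
    size: int = CANDIDATE_SIZE,
) -> CandidateList:
    """Position-free fallback: the test gene plus uniformly sampled decoys.

    Decoys are drawn without replacement from non-disease network genes.
    This departs from chromosome-local lists and exists so the harness can
    run without a genomic-position table.
    """
    pool = sorted(set(net.nodes) - partition.D - {test_gene})
    k = min(size - 1, len(pool))
    decoys = rng.choice(len(pool), size=k, replace=False)
    cands = (test_gene,) + tuple(pool[i] for i in sorted(decoys))
    return CandidateList(test_gene=test_gene, candidates=cands)


def _run_trial(
    disease: str,
    test_gene: str,
    training: list[str],
    net: AnnotatedNetwork,
    partition: GenePartition,
    config: PropagationConfig,
    mode: str,
    positions: pd.DataFrame | None,
    rng: np.random.Generator | None,
    size: int,
) -> TrialResult:
    if test_gene not in net:
        return TrialResult(
            disease=disease,
            test_gene=test_gene,
            rank=size,
            enrichment=50.0 / size,
            on_network=False,
            n_candidates=size,
        )
    if positions is not None:
        clist = build_candidate_list(test_gene, positions, size=size)
    else:
        assert rng is not None, "positions or rng required"
        clist = random_candidate_list(test_gene, net, partition, rng, size=size)
    ranked = score_candidates(
        net,
        mode,
        T_h=training,
        E_minus=partition.E_minus,
        config=config,
        candidates=list(clist.candidates),
    )
    rank = next(r for g, _s, r in ranked if g == test_gene)
    return TrialResult(
        disease=disease,
        test_gene=test_gene,
        rank=rank,
        enrichment=50.0 / rank,
        on_network=True,
        n_candidates=len(clist.candidates),
    )


def loocv(
    disease_gene_map: dict[str, list[str]],
    net: AnnotatedNetwork,
    partition: GenePartition,
    config: PropagationConfig = PropagationConfig(),
    positions: pd.DataFrame | None = None,
    mode: str = "np_de",
    candidate_size: int = CANDIDATE_SIZE,
    seed: int = 0,
) -> EvaluationReport:
    """Leave-one-out evaluation over every (disease, gene) pair.

    For each disease with m >= 2 genes, each gene is held out in turn and
    ranked with the remaining m-1 genes as the positive training prior; the
    negative E- prior is fixed from the full disease annotation (held-out
    genes are disease genes, so they never enter E-).  Diseases with a
    single gene are skipped with a warning.  Without a positions table,
    decoys are sampled with the given seed.
    """
    rng = np.random.default_rng(seed) if positions is None else None
    trials: list[TrialResult] = []
    for disease in sorted(disease_gene_map):
        genes = list(dict.fromkeys(disease_gene_map[disease]))
        if len(genes) < 2:
            warnings.warn(f"disease {disease!r} has fewer than 2 genes; skipped", stacklevel=2)
            continue
        for test_gene in genes:
            training = [g for g in genes if g != test_gene]
            trials.append(
                _run_trial(
                    disease, test_gene, training, net, partition, config, mode,
                    positions, rng, candidate_size,
                )
            )
    return EvaluationReport.from_trials(trials, mode=mode)


def time_split_evaluate(
    train_map: dict[str, list[str]],
    test_map: dict[str, list[str]],
    net: AnnotatedNetwork,
    partition: GenePartition,
    config: PropagationConfig = PropagationConfig(),
    positions: pd.DataFrame | None = None,
    mode: str = "np_de",
    candidate_size: int = CANDIDATE_SIZE,
    seed: int = 0,
) -> EvaluationReport:
    """Fixed train/test split per disease (e.g. genes verified before vs after a year)."""
    rng = np.random.default_rng(seed) if positions is None else None
    trials: list[TrialResult] = []
    for disease in sorted(test_map):
        test_genes = list(dict.fromkeys(test_map.get(disease, [])))
        training = list(dict.fromkeys(train_map.get(disease, [])))
        if not test_genes or not training:
            warnings.warn(
                f"disease {disease!r} lacks a train or test set; skipped", stacklevel=2
            )
            continue
        overlap = set(test_genes) & set(training)
        if overlap:
            raise ValueError(
                f"disease {disease!r}: train and test sets overlap on {sorted(overlap)}"
            )
        for test_gene in test_genes:
            trials.append(
                _run_trial(
                    disease, test_gene, training, net, partition, config, mode,
                    positions, rng, candidate_size,
                )
            )
    return EvaluationReport.from_trials(trials, mode=mode)


def roc_auc(
    trials,
    candidate_size: int = CANDIDATE_SIZE,
) -> tuple[tuple[tuple[float, float], ...], float]:
    """ROC points and trapezoidal AUC over rank thresholds 0..candidate_size.

    Off-network trials are excluded.  At threshold t, sensitivity is the
    fraction of test genes ranked within t; the false-positive rate is the
    mean over trials of the fraction of decoy candidates ranked within t.
    Returns ((fpr, sensitivity), ...) and the AUC.
    """
    on = [t for t in trials if t.on_network]
    if not on:
        raise ValueError("ROC analysis requires at least one on-network trial")
    points = []
    for thr in range(0, candidate_size + 1):
        sens = float(np.mean([t.rank <= thr for t in on]))
        fprs = []
        for t in on:
            n_c = t.n_candidates
            decoys_in = min(thr, n_c) - (1 if t.rank <= thr else 0)
            fprs.append(decoys_in / max(n_c - 1, 1))
        points.append((float(np.mean(fprs)), sens))
    points.sort()
    xs = np.array([p[0] for p in points])
    ys = np.array([p[1] for p in points])
    auc = float(np.trapezoid(ys, xs))
    return tuple(points), auc
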
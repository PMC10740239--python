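"""Probabilistic record linkage with graph clustering.

Records are compared on identity fields (names, date of birth, sex,
province, facility) with a weighted similarity score; pairs scoring at
or above a match threshold become edges of an undirected graph whose
connected components are the asserted patient identities. Blocking
(candidate generation restricted to records sharing sex plus either
birth year or surname initial) keeps pair comparison tractable.

The assignment is evaluated against ground truth with the standard
pairwise metrics: sensitivity (share of true co-referent record pairs
recovered) and positive predictive value (share of asserted pairs that
are truly co-referent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import networkx as nx
import numpy as np
import pandas as pd

IDENTITY_FIELDS = ("given_name", "family_name", "dob", "sex", "province", "facility")


def _default_weights():
    return {"given_name": 0.3, "family_name": 0.3, "dob": 0.2,
            "sex": 0.1, "province": 0.05, "facility": 0.05}


@dataclass
class LinkageConfig:
    """Scoring and clustering parameters.

    ``field_weights`` must sum to 1; the pair score is the weighted sum
    of per-field similarities, so it lives in [0, 1]. Name similarity is
    a normalized Levenshtein similarity (1 - distance / max length),
    case-insensitive. Date of birth scores 1 on exact match; with
    ``dob_partial_credit`` a date differing in exactly one of
    day/month/year scores 0.5 (tolerating single-component errors).
    Sex, province and facility are exact-match fields.
    """

    field_weights: dict = field(default_factory=_default_weights)
    name_similarity: str = "levenshtein"
    match_threshold: float = 0.85
    blocking_keys: list = field(default_factory=lambda: [
        ("sex", "birth_year"), ("sex", "surname_initial")])
    dob_partial_credit: bool = True
    refine_components: bool = True
    max_component_inconsistency: float = 0.5

    def validate(self) -> None:
        if set(self.field_weights) - set(IDENTITY_FIELDS):
            raise ValueError(f"unknown fields in weights: "
                             f"{set(self.field_weights) - set(IDENTITY_FIELDS)}")
        if any(w < 0 for w in self.field_weights.values()):
            raise ValueError("field weights must be nonnegative")
        if abs(sum(self.field_weights.values()) - 1.0) > 1e-9:
            raise ValueError("field weights must sum to 1")
        if not 0.0 <= self.match_threshold <= 1.0:
            raise ValueError("match_threshold must be in [0, 1]")
        if not 0.0 <= self.max_component_inconsistency <= 1.0:
            raise ValueError("max_component_inconsistency must be in [0, 1]")


@dataclass
class IdentityCluster:
    cluster_id: str
    record_ids: frozenset


@dataclass
class LinkageEvaluation:
    """Pairwise linkage metrics against a ground-truth partition."""

    sensitivity: float
    ppv: float
    n_true_pairs: int
    n_predicted_pairs: int
    n_true_positive_pairs: int
    degenerate_ppv: bool = False  # no predicted pairs; PPV reported as 1


def name_similarity(a: str, b: str) -> float:
    """Normalized Levenshtein similarity on lowercased strings."""
    a, b = (a or "").lower(), (b or "").lower()
    if not a or not b:
        return 0.0
    if a == b:
        return 1.0
    d = edlib.align(a, b, task="distance")["editDistance"]
    return max(0.0, 1.0 - d / max(len(a), len(b)))


def dob_similarity(a, b, partial_credit: bool = True) -> float:
    a, b = pd.Timestamp(a), pd.Timestamp(b)
    if pd.isna(a) or pd.isna(b):
        return 0.0
    if a == b:
        return 1.0
    if partial_credit:
        diffs = (a.day != b.day) + (a.month != b.month) + (a.year != b.year)
        if diffs == 1:
            return 0.5
    return 0.0


def score_pair(a, b, config: LinkageConfig | None = None) -> float:
    """Weighted identity similarity between two records (symmetric).

    ``a`` and ``b`` are mappings with the identity fields (``facility``
    may be given as ``facility_id``).
    """
    config = config or LinkageConfig()
    w = config.field_weights

    def fac(r):
        return r.get("facility", r.get("facility_id", ""))

    score = 0.0
    score += w.get("given_name", 0) * name_similarity(a.get("given_name", ""), b.get("given_name", ""))
    score += w.get("family_name", 0) * name_similarity(a.get("family_name", ""), b.get("family_name", ""))
    score += w.get("dob", 0) * dob_similarity(a.get("dob"), b.get("dob"), config.dob_partial_credit)
    score += w.get("sex", 0) * float(a.get("sex") == b.get("sex"))
    score += w.get("province", 0) * float(a.get("province") == b.get("province"))
    score += w.get("facility", 0) * float(fac(a) == fac(b))
    return score


# ---------------------------------------------------------------------------
# Candidate generation and vectorized scoring


def _blocking_values(records: pd.DataFrame, key: str) -> pd.Series:
    if key == "birth_year":
        return pd.to_datetime(records["dob"]).dt.year.astype("Int64").astype(str)
    if key == "surname_initial":
        return records["family_name"].fillna("").str.slice(0, 1).str.lower()
    if key in records.columns:
        return records[key].astype(str)
    raise ValueError(f"unknown blocking key component {key!r}")


def block_candidates(records: pd.DataFrame,
                     config: LinkageConfig | None = None) -> np.ndarray:
    """Positional index pairs (i, j), i < j, sharing a blocking key.

    Records with missing sex or dob are never candidates (they cannot be
    scored) and end up as singleton clusters.
    """
    config = config or LinkageConfig()
    usable = (records["sex"].notna() & (records["sex"].astype(str) != "")
              & pd.to_datetime(records["dob"], errors="coerce").notna()).to_numpy()
    frame_pos = np.flatnonzero(usable)
    chunks = []
    for combo in config.blocking_keys:
        key = pd.DataFrame({k: _blocking_values(records, k).to_numpy() for k in combo})
        key = key.iloc[frame_pos].reset_index(drop=True)
        grouped = key.groupby(list(combo), sort=False).indices
        for idx in grouped.values():
            fp = np.sort(frame_pos[np.asarray(idx)])
            if len(fp) > 1:
                a, b = np.triu_indices(len(fp), k=1)
                chunks.append(np.column_stack([fp[a], fp[b]]))
    if not chunks:
        return np.empty((0, 2), dtype=int)
    pairs = np.concatenate(chunks)
    # dedupe pairs generated by more than one blocking key
    code = pairs[:, 0].astype(np.int64) * len(records) + pairs[:, 1]
    _, keep = np.unique(code, return_index=True)
    return pairs[np.sort(keep)]


def score_pairs(records: pd.DataFrame, pairs: np.ndarray,
                config: LinkageConfig | None = None) -> np.ndarray:
    """Vectorized scores for candidate pairs.

    Exact-match fields are compared with numpy; name similarities are
    computed once per unique (string, string) combination, which is what
    makes national-scale name pools tractable.
    """
    config = config or LinkageConfig()
    if len(pairs) == 0:
        return np.empty(0)
    w = config.field_weights
    i, j = pairs[:, 0], pairs[:, 1]
    score = np.zeros(len(pairs))

    for col, wkey in (("sex", "sex"), ("province", "province"),
                      ("facility_id", "facility")):
        codes, _ = pd.factorize(records[col].astype(str))
        score += w.get(wkey, 0) * (codes[i] == codes[j])

    dob = pd.to_datetime(records["dob"])
    day, mon, yr = dob.dt.day.to_numpy(), dob.dt.month.to_numpy(), dob.dt.year.to_numpy()
    ndiff = ((day[i] != day[j]).astype(int) + (mon[i] != mon[j]).astype(int)
             + (yr[i] != yr[j]).astype(int))
    dob_sim = np.where(ndiff == 0, 1.0,
                       np.where((ndiff == 1) & config.dob_partial_credit, 0.5, 0.0))
    score += w.get("dob", 0) * dob_sim

    # Name fields: factorize to integer codes, then evaluate the edit
    # similarity once per unique unordered code pair — pairs vastly
    # outnumber distinct name combinations, and keeping the per-pair
    # arrays purely numeric bounds memory at national scale.
    for col, wkey in (("given_name", "given_name"), ("family_name", "family_name")):
        codes, uniques = pd.factorize(
            records[col].fillna("").astype(str).str.lower())
        a, b = codes[i], codes[j]
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        key = lo.astype(np.int64) * len(uniques) + hi
        uniq_keys = np.unique(key)
        sims = np.empty(len(uniq_keys))
        n_u = len(uniques)
        for t, k in enumerate(uniq_keys):
            ka, kb = divmod(int(k), n_u)
            sims[t] = name_similarity(uniques[ka], uniques[kb])
        score += w.get(wkey, 0) * sims[np.searchsorted(uniq_keys, key)]
    return score


# ---------------------------------------------------------------------------
# Clustering


def _refine(g: nx.Graph, n_nodes: int, pairs: np.ndarray, scores: np.ndarray,
            config: LinkageConfig) -> None:
    """Split inconsistent components by removing lowest-scoring edges.

    A component is inconsistent when the fraction of its internal
    candidate pairs scoring below the match threshold exceeds
    ``max_component_inconsistency``. Each pass removes the weakest
    match edge from every offending component of size > 2, until all
    components comply. Mutates ``g``.
    """
    i, j = pairs[:, 0], pairs[:, 1]
    below = scores < config.match_threshold
    while True:
        label = np.empty(n_nodes, dtype=np.int64)
        n_comp = 0
        for comp in nx.connected_components(g):
            label[list(comp)] = n_comp
            n_comp += 1
        sizes = np.bincount(label, minlength=n_comp)
        internal = label[i] == label[j]
        lab_int = label[i[internal]]
        n_internal = np.bincount(lab_int, minlength=n_comp)
        n_below = np.bincount(lab_int[below[internal]], minlength=n_comp)
        with np.errstate(invalid="ignore"):
            frac = np.where(n_internal > 0, n_below / np.maximum(n_internal, 1), 0.0)
        offending = set(np.flatnonzero(
            (frac > config.max_component_inconsistency) & (sizes > 2)))
        if not offending:
            return
        weakest: dict = {}
        for u, v, s in g.edges(data="score"):
            c = label[u]
            if c in offending and (c not in weakest or s < weakest[c][2]):
                weakest[c] = (u, v, s)
        if not weakest:
            return
        for u, v, _s in weakest.values():
            g.remove_edge(u, v)


def cluster_records(records: pd.DataFrame,
                    config: LinkageConfig | None = None,
                    pairs: np.ndarray | None = None,
                    scores: np.ndarray | None = None) -> pd.DataFrame:
    """Partition records into patient clusters.

    Builds the match graph from candidate pairs scoring at or above the
    threshold and takes connected components. With
    ``config.refine_components`` enabled, any component in which the
    fraction of internal candidate pairs scoring *below* the threshold
    exceeds ``max_component_inconsistency`` is split by removing its
    lowest-scoring edges until every component complies — this guards
    against transitive over-merging through chains of borderline
    matches.

    Returns a DataFrame with columns ``record_id``, ``cluster_id``; the
    clusters always partition the input records.
    """
    config = config or LinkageConfig()
    config.validate()
    if pairs is None:
        pairs = block_candidates(records, config)
    if scores is None:
        scores = score_pairs(records, pairs, config)

    g = nx.Graph()
    g.add_nodes_from(range(len(records)))
    match = scores >= config.match_threshold
    for (i, j), s in zip(pairs[match], scores[match]):
        g.add_edge(int(i), int(j), score=float(s))

    if config.refine_components and len(pairs):
        _refine(g, len(records), pairs, scores, config)
    components = [set(c) for c in nx.connected_components(g)]

    cluster_of = {}
    for cid, comp in enumerate(sorted(components, key=min)):
        for node in comp:
            cluster_of[node] = f"c{cid:07d}"
    rid = records["record_id"].to_numpy()
    return pd.DataFrame({
        "record_id": rid,
        "cluster_id": [cluster_of[k] for k in range(len(records))],
    })


def clusters_as_list(mapping: pd.DataFrame) -> list[IdentityCluster]:
    return [IdentityCluster(cid, frozenset(sub["record_id"]))
            for cid, sub in mapping.groupby("cluster_id", sort=True)]


# ---------------------------------------------------------------------------
# Evaluation


def _pair_count(sizes) -> int:
    sizes = np.asarray(sizes, dtype=np.int64)
    return int((sizes * (sizes - 1) // 2).sum())


def evaluate_linkage(mapping: pd.DataFrame,
                     record_map: pd.DataFrame) -> LinkageEvaluation:
    """Pairwise sensitivity and PPV of a clustering against truth.

    ``mapping`` holds record_id -> cluster_id, ``record_map`` holds
    record_id -> true_patient_id; they must cover exactly the same
    records. With zero predicted pairs PPV is reported as 1 and flagged
    (``degenerate_ppv``) — there are no asserted pairs to be wrong.
    """
    pred = mapping.set_index("record_id")["cluster_id"]
    true = record_map.set_index("record_id")["true_patient_id"]
    if set(pred.index) != set(true.index) or pred.index.duplicated().any():
        raise ValueError("clusters do not partition the records in the ground truth")

    joint = pd.DataFrame({"pred": pred, "true": true.reindex(pred.index)})
    n_true = _pair_count(joint.groupby("true").size())
    n_pred = _pair_count(joint.groupby("pred").size())
    n_tp = _pair_count(joint.groupby(["pred", "true"]).size())

    sensitivity = n_tp / n_true if n_true else 1.0
    degenerate = n_pred == 0
    ppv = 1.0 if degenerate else n_tp / n_pred
    return LinkageEvaluation(
        sensitivity=sensitivity, ppv=ppv, n_true_pairs=n_true,
        n_predicted_pairs=n_pred, n_true_positive_pairs=n_tp,
        degenerate_ppv=degenerate,
    )
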
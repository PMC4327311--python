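"""Reconstruction of unknown F1 parents by iterative kinship matching.

Hybrid panels rarely come with both parents sequenced.  Because every F1
carries one allele from each parent at every site, an observed parent plus
the hybrid genotype determines the other parent's genotype everywhere except
at sites where the pair is Mendelian-inconsistent (opposite homozygotes —
impossible for a true parent absent genotyping error) or uncalled.  Newly
deduced parents join the panel, which lets hybrids sharing that parent be
resolved in the next round; a handful of iterations resolves cascades in
which one popular female line anchors dozens of crosses.

Conflicted or missing sites of a deduced parent are filled by majority
consensus across all hybrids sharing that parent — the same information a
phasing-based fill would use, without requiring phased data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    MISSING,
    GenotypeMatrix,
    cross_matching,
    matching_kinship,
)


@dataclass
class ParentAssignment:
    """Resolution record for one hybrid."""

    hybrid: str
    candidate_parent: str
    kinship: float
    conflict_rate: float
    other_parent: str
    iteration: int


@dataclass
class ParentPanel:
    """A panel of (observed or inferred) inbred parental genotypes."""

    ids: list[str]
    codes: np.ndarray  # (n_parents, n_sites), homozygous or missing
    provenance: dict[str, str] = field(default_factory=dict)  # id -> observed|inferred
    support: dict[str, list[np.ndarray]] = field(default_factory=dict)
    support_hybrids: dict[str, list[str]] = field(default_factory=dict)
    redundancy_groups: list[list[str]] = field(default_factory=list)

    @classmethod
    def from_matrix(cls, matrix: GenotypeMatrix) -> "ParentPanel":
        return cls(
            ids=list(matrix.individuals),
            codes=matrix.codes.copy(),
            provenance={i: "observed" for i in matrix.individuals},
        )

    @property
    def n_parents(self) -> int:
        return len(self.ids)

    def genotypes_of(self, parent_id: str) -> np.ndarray:
        return self.codes[self.ids.index(parent_id)]

    def append(self, parent_id: str, codes: np.ndarray, provenance: str) -> None:
        self.codes = np.vstack([self.codes, codes.astype(np.int8)])
        self.ids.append(parent_id)
        self.provenance[parent_id] = provenance


# ---------------------------------------------------------------------------
# Candidate scoring
# ---------------------------------------------------------------------------

def _conflict_matrix(hybrid_codes: np.ndarray, panel_codes: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Opposite-homozygote conflict rates between hybrids and panel members.

    Returns (conflict_rate, kinship) arrays of shape (n_hybrids, n_parents).
    """
    h, p = hybrid_codes, panel_codes
    h0 = (h == 0).astype(np.float64)
    h2 = (h == 2).astype(np.float64)
    p0 = (p == 0).astype(np.float64)
    p2 = (p == 2).astype(np.float64)
    conflicts = h0 @ p2.T + h2 @ p0.T
    called = (h != MISSING).astype(np.float64) @ (p != MISSING).T.astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(called > 0, conflicts / called, np.nan)
    kin = cross_matching(h, p)
    return rate, kin


def score_candidates(hybrid: np.ndarray, panel: ParentPanel) -> pd.DataFrame:
    """Rank panel members as candidate parents of one hybrid.

    Sorted by kinship (descending), breaking ties by lower conflict rate and
    then lexicographic ID.  The conflict rate is the fraction of
    pairwise-called sites where hybrid and candidate are opposite homozygotes
    — a Mendelian impossibility for a true parent absent genotype error.
    """
    if panel.n_parents == 0:
        raise ValueError("empty parent panel")
    rate, kin = _conflict_matrix(np.asarray(hybrid)[None, :], panel.codes)
    df = pd.DataFrame(
        {"parent": panel.ids, "kinship": kin[0], "conflict_rate": rate[0]}
    )
    return df.sort_values(
        ["kinship", "conflict_rate", "parent"], ascending=[False, True, True]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Deduction of the other parent
# ---------------------------------------------------------------------------

def deduce_other_parent(
    hybrid: np.ndarray, candidate: np.ndarray, max_het_fraction: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Given hybrid and one (homozygous) parent, deduce the other parent.

    Deduction table per site (hybrid, parent) -> other parent:
    (1, 0) -> 2, (1, 2) -> 0, (0, 0) -> 0, (2, 2) -> 2.  Opposite-homozygote
    conflicts, parent-missing, parent-heterozygous and hybrid-missing sites
    are masked (MISSING in the vector, True in the returned mask).

    Raises ``ValueError`` if the candidate is heterozygous at more than
    ``max_het_fraction`` of its called sites (not a plausible inbred parent).
    """
    h = np.asarray(hybrid)
    p = np.asarray(candidate)
    if h.shape != p.shape:
        raise ValueError("vectors must have equal length")
    p_called = p != MISSING
    if p_called.any():
        het_frac = float((p[p_called] == 1).sum() / p_called.sum())
        if het_frac > max_het_fraction:
            raise ValueError(
                f"candidate heterozygous at {het_frac:.1%} of sites; rejected"
            )
    other = np.full(h.shape, MISSING, dtype=np.int8)
    other[(h == 1) & (p == 0)] = 2
    other[(h == 1) & (p == 2)] = 0
    other[(h == 0) & (p == 0)] = 0
    other[(h == 2) & (p == 2)] = 2
    mask = other == MISSING
    return other, mask


def consensus_fill(vectors: list[np.ndarray]) -> np.ndarray:
    """Majority-vote merge of deduced genotype vectors sharing one parent.

    Per site the most frequent non-missing code wins; ties and all-masked
    sites stay missing.
    """
    if not vectors:
        raise ValueError("need at least one vector")
    V = np.vstack(vectors)
    counts = np.stack([(V == c).sum(axis=0) for c in (0, 1, 2)])  # (3, m)
    best = counts.max(axis=0)
    argbest = counts.argmax(axis=0)
    n_at_best = (counts == best).sum(axis=0)
    merged = np.where((best > 0) & (n_at_best == 1), argbest, MISSING)
    return merged.astype(np.int8)


# ---------------------------------------------------------------------------
# Iterative reconstruction
# ---------------------------------------------------------------------------

def iterate_reconstruction(
    hybrids: GenotypeMatrix,
    observed_panel: GenotypeMatrix,
    max_iter: int = 4,
    accept_ceiling: float = 0.02,
    match_threshold: float = 0.9,
) -> tuple[list[ParentAssignment], ParentPanel]:
    """Multi-round parental reconstruction.

    Each round scores every unresolved hybrid against the current panel; the
    top-kinship candidate is accepted when its opposite-homozygote conflict
    rate is at most ``accept_ceiling``.  The other parent is deduced, newly
    deduced parents are clustered (simple matching >= ``match_threshold``
    marks "same line") and consensus-merged into panel entries, and the next
    round re-scores the remaining hybrids against the grown panel.  Stops at
    ``max_iter`` rounds or when a round resolves nothing.  Unresolved hybrids
    are simply absent from the assignment list — a valid outcome.
    """
    panel = ParentPanel.from_matrix(observed_panel)
    assignments: list[ParentAssignment] = []
    unresolved = list(range(hybrids.n_individuals))
    n_new = 0

    for iteration in range(1, max_iter + 1):
        if not unresolved:
            break
        hcodes = hybrids.codes[unresolved]
        rate, kin = _conflict_matrix(hcodes, panel.codes)
        accepted: list[tuple[int, int, float, float, np.ndarray, np.ndarray]] = []
        for row, hidx in enumerate(unresolved):
            order = np.lexsort(
                (np.array(panel.ids, dtype=object), rate[row], -kin[row])
            )
            best = order[0]
            if not np.isfinite(rate[row, best]) or rate[row, best] > accept_ceiling:
                continue
            other, mask = deduce_other_parent(
                hybrids.codes[hidx], panel.codes[best]
            )
            accepted.append(
                (hidx, best, float(kin[row, best]), float(rate[row, best]),
                 other, mask)
            )
        if not accepted:
            break

        # attach each deduced vector to an existing or new panel entry
        deduced = np.vstack([a[4] for a in accepted])
        to_panel = cross_matching(deduced, panel.codes)
        labels: list[str | None] = [None] * len(accepted)
        with np.errstate(invalid="ignore"):
            for i in range(len(accepted)):
                sims = to_panel[i]
                j = int(np.nanargmax(sims)) if np.isfinite(sims).any() else -1
                if j >= 0 and sims[j] >= match_threshold:
                    labels[i] = panel.ids[j]
        # cluster the unmatched deductions among themselves (single linkage)
        open_idx = [i for i, l in enumerate(labels) if l is None]
        if open_idx:
            sub = deduced[open_idx]
            sim = cross_matching(sub, sub)
            comp = _single_linkage(sim, match_threshold)
            for cid in sorted(set(comp)):
                members = [open_idx[i] for i in range(len(open_idx)) if comp[i] == cid]
                n_new += 1
                new_id = f"P{iteration}_{n_new:03d}"
                merged = consensus_fill([deduced[i] for i in members])
                panel.append(new_id, merged, "inferred")
                panel.support[new_id] = [accepted[i][4] for i in members]
                panel.support_hybrids[new_id] = [
                    hybrids.individuals[accepted[i][0]] for i in members
                ]
                for i in members:
                    labels[i] = new_id

        for (hidx, best, k, r, other, mask), label in zip(accepted, labels):
            assert label is not None
            if panel.provenance.get(label) == "inferred" and label in panel.support:
                if other is not panel.support[label][0] and not any(
                    other is v for v in panel.support[label]
                ):
                    panel.support[label].append(other)
                    panel.support_hybrids[label].append(hybrids.individuals[hidx])
            assignments.append(
                ParentAssignment(
                    hybrid=hybrids.individuals[hidx],
                    candidate_parent=panel.ids[best],
                    kinship=k,
                    conflict_rate=r,
                    other_parent=label,
                    iteration=iteration,
                )
            )
        resolved_ids = {a[0] for a in accepted}
        unresolved = [i for i in unresolved if i not in resolved_ids]
        # refresh consensus of inferred parents with all accumulated support
        for pid, vecs in panel.support.items():
            panel.codes[panel.ids.index(pid)] = consensus_fill(vecs)

    return assignments, panel


def _single_linkage(sim: np.ndarray, threshold: float) -> np.ndarray:
    """Connected components of the >= threshold similarity graph."""
    n = sim.shape[0]
    comp = np.arange(n)

    def find(i: int) -> int:
        while comp[i] != i:
            comp[i] = comp[comp[i]]
            i = comp[i]
        return i

    with np.errstate(invalid="ignore"):
        edges = np.argwhere(np.nan_to_num(sim, nan=-1.0) >= threshold)
    for i, j in edges:
        ri, rj = find(int(i)), find(int(j))
        if ri != rj:
            comp[rj] = ri
    return np.array([find(i) for i in range(n)])


# ---------------------------------------------------------------------------
# Deduplication & evaluation
# ---------------------------------------------------------------------------

def deduplicate_parents(
    panel: ParentPanel, similarity_threshold: float = 0.99
) -> ParentPanel:
    """Collapse near-identical panel entries into non-redundant lines.

    Single-linkage clustering at simple matching >= ``similarity_threshold``;
    each cluster is represented by the consensus of its members, named after
    the lexicographically first member (observed members preferred).
    """
    sim = cross_matching(panel.codes, panel.codes)
    comp = _single_linkage(sim, similarity_threshold)
    new = ParentPanel(ids=[], codes=np.empty((0, panel.codes.shape[1]), np.int8))
    groups: list[list[str]] = []
    for cid in sorted(set(comp), key=lambda c: min(
        panel.ids[i] for i in np.flatnonzero(comp == c)
    )):
        members = [i for i in range(panel.n_parents) if comp[i] == cid]
        ids = [panel.ids[i] for i in members]
        observed = sorted(
            i for i in ids if panel.provenance.get(i) == "observed"
        )
        rep_id = observed[0] if observed else sorted(ids)[0]
        merged = consensus_fill([panel.codes[i] for i in members])
        prov = "observed" if observed else "inferred"
        new.append(rep_id, merged, prov)
        if prov == "inferred":
            sup_v, sup_h = [], []
            for i in ids:
                sup_v.extend(panel.support.get(i, []))
                sup_h.extend(panel.support_hybrids.get(i, []))
            new.support[rep_id] = sup_v
            new.support_hybrids[rep_id] = sup_h
        groups.append(ids)
    new.redundancy_groups = groups
    return new


def evaluate_agreement(panel: ParentPanel, truth) -> tuple[pd.DataFrame, float]:
    """Per-parent and site-weighted overall agreement of inferred parents
    with the ground-truth genotypes (synthetic runs only).

    Each inferred panel entry is mapped to the true parent it supports: among
    the true mothers/fathers of its supporting hybrids, the one whose
    genotype matches the inferred vector best.  Agreement is computed over
    called, unmasked sites of the inferred vector.
    """
    trio_by_hybrid = {t.hybrid: t for t in truth.trios}
    rows = []
    total_match = 0.0
    total_sites = 0.0
    for pid in panel.ids:
        if panel.provenance.get(pid) != "inferred":
            continue
        vec = panel.genotypes_of(pid)
        cands: set[str] = set()
        for h in panel.support_hybrids.get(pid, []):
            t = trio_by_hybrid.get(h)
            if t is None:
                raise KeyError(f"hybrid {h} absent from truth trios")
            cands.update([t.mother, t.father])
        if not cands:
            continue
        best_id, best_sim = None, -1.0
        for cand in sorted(cands):
            sim = matching_kinship(vec, truth.parent_genotypes(cand))
            if sim > best_sim:
                best_id, best_sim = cand, sim
        true_vec = truth.parent_genotypes(best_id)
        both = (vec != MISSING) & (true_vec != MISSING)
        n = int(both.sum())
        match = int((vec[both] == true_vec[both]).sum())
        rows.append((pid, best_id, n, match / n if n else np.nan))
        total_match += match
        total_sites += n
    per_parent = pd.DataFrame(
        rows, columns=["inferred_parent", "true_parent", "n_sites", "agreement"]
    )
    overall = total_match / total_sites if total_sites else float("nan")
    return per_parent, overall
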
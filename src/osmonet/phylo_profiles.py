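"""Phylogenetic profiles and co-evolution-based recruitment.

A gene's phylogenetic profile is the binary string a_1..a_n over a panel of
n reference genomes, a_j = 1 when the gene has a detectable ortholog in
genome j. Genes with highly similar profiles tend to be functionally
related, so profile similarity is used as one guilt-by-association channel.

The functional-relatedness measure combines the Hamming distance d_H
between two profiles with the number h of genomes carrying orthologs of
both genes:

    score(g_i, g_j) = (h + 1) / (1 + d_H)**alpha        (alpha = 2 default)

NOTE: this closed form is a reconstruction. The measure it implements is
specified by its ingredients and monotonicity requirements (decreasing in
d_H, non-decreasing in h, alpha-weighted), which the reconstruction
satisfies; it is a single pluggable function so an alternative form drops
in. The per-gene profile log-likelihood LH (under independent per-genome
presence frequencies) enters only as an informativeness filter: profiles
whose |LH| falls below a configurable percentile are too generic to carry
co-evolution signal and are excluded from recruitment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from osmonet.errors import ConfigurationError, DimensionError
from osmonet.template_mapping import NetworkModel


@dataclass
class PhyloProfile:
    """Binary presence/absence vector of one gene over the genome panel."""

    gene: str
    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.int8)
        if self.bits.ndim != 1:
            raise DimensionError("profile must be a 1-D bit vector")
        if not np.isin(self.bits, (0, 1)).all():
            raise DimensionError("profile entries must be 0/1")

    def __len__(self) -> int:
        return len(self.bits)


@dataclass
class PanelMarginals:
    """Per-genome ortholog counts m_j over the target-gene universe.

    ``n`` is the panel size (number of reference genomes); ``m[j]`` counts
    target genes with an ortholog in genome j; ``n_genes`` is the number of
    target genes, the denominator of the presence frequency p_j = m_j/n_genes.
    """

    n: int
    m: np.ndarray
    n_genes: int

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=np.int64)
        if self.m.shape != (self.n,):
            raise DimensionError(f"need {self.n} marginals, got {self.m.shape}")
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if (self.m < 0).any() or (self.m > self.n_genes).any():
            raise ConfigurationError("marginals must lie in [0, n_genes]")

    @classmethod
    def from_matrix(cls, profiles: pd.DataFrame) -> "PanelMarginals":
        """Column sums of a gene x genome 0/1 matrix."""
        mat = profiles.to_numpy(dtype=np.int64)
        return cls(n=mat.shape[1], m=mat.sum(axis=0), n_genes=mat.shape[0])

    def presence_freq(self) -> np.ndarray:
        """p_j clamped away from {0, 1} so log-likelihoods stay finite."""
        eps = 1.0 / (2.0 * self.n_genes)
        return np.clip(self.m / self.n_genes, eps, 1.0 - eps)


@dataclass
class RelatednessParams:
    """Weighting factor alpha and the informativeness-filter percentile.

    ``lh_percentile`` = q excludes from recruitment the q% of genes whose
    profile |log-likelihood| is smallest (most generic profiles); 0 disables
    the filter (the default — every gene competes).
    """

    alpha: float = 2.0
    lh_percentile: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ConfigurationError("alpha must be > 0")
        if not 0.0 <= self.lh_percentile < 100.0:
            raise ConfigurationError("lh_percentile must be in [0, 100)")


def profile_likelihood(p: PhyloProfile, marg: PanelMarginals) -> float:
    """Log-likelihood of a profile under independent per-genome frequencies.

    LH_i = sum_j log p_j with p_j the panel presence frequency of genome j
    when the gene is present there and 1 - p_j otherwise.
    """
    if len(p) != marg.n:
        raise DimensionError(
            f"profile length {len(p)} != panel size {marg.n}")
    freq = marg.presence_freq()
    probs = np.where(p.bits == 1, freq, 1.0 - freq)
    return float(np.log(probs).sum())


def _default_relatedness(h: float, d_h: float, alpha: float) -> float:
    return (h + 1.0) / (1.0 + d_h) ** alpha


def phylo_relatedness(
    g_i: PhyloProfile,
    g_j: PhyloProfile,
    marg: PanelMarginals | None = None,
    params: RelatednessParams | None = None,
    form: Callable[[float, float, float], float] = _default_relatedness,
) -> float:
    """Functional relatedness of two genes from their profiles.

    Symmetric; strictly decreasing in the Hamming distance d_H at fixed h;
    non-decreasing in the shared-presence count h at fixed d_H. ``form`` is
    the pluggable closed form (see module docstring).
    """
    if len(g_i) == 0 or len(g_j) == 0:
        raise DimensionError("zero-length profiles")
    if len(g_i) != len(g_j):
        raise DimensionError("profiles of unequal length")
    params = params or RelatednessParams()
    d_h = int(np.count_nonzero(g_i.bits != g_j.bits))
    h = int(np.count_nonzero((g_i.bits == 1) & (g_j.bits == 1)))
    return float(form(h, d_h, params.alpha))


def relatedness_matrix(
    bits_a: np.ndarray,
    bits_b: np.ndarray,
    alpha: float = 2.0,
) -> np.ndarray:
    """Pairwise relatedness between the rows of two 0/1 matrices.

    Vectorised equivalent of :func:`phylo_relatedness` under the default
    closed form; rows of ``bits_a`` index the first axis of the result.
    """
    a = np.asarray(bits_a, dtype=np.float64)
    b = np.asarray(bits_b, dtype=np.float64)
    h = a @ b.T
    ra = a.sum(axis=1)[:, None]
    rb = b.sum(axis=1)[None, :]
    d_h = ra + rb - 2.0 * h
    return (h + 1.0) / (1.0 + d_h) ** alpha


@dataclass(frozen=True)
class ProfileRecruit:
    gene: str
    anchor: str
    score: float


@dataclass
class ProfileRecruitment:
    recruits: list[ProfileRecruit]
    skipped_model_genes: list[str] = field(default_factory=list)

    def genes(self) -> set[str]:
        return {r.gene for r in self.recruits}


def recruit_by_profile(
    model: NetworkModel,
    profiles: pd.DataFrame,
    marg: PanelMarginals | None = None,
    params: RelatednessParams | None = None,
) -> ProfileRecruitment:
    """Recruit genes more related to a model gene than any other model gene.

    A non-model gene x is recruited via anchor g iff
    score(x, g) > max over model genes g' != g of score(g', g);
    i.e. x beats every competing model gene for g's co-evolution signal.
    A one-gene model defines no competing bar, so nothing is recruited.

    ``profiles`` is the gene x genome 0/1 matrix for all target genes.
    Model genes without a profile row are skipped with a warning entry in
    the result; candidates below the |LH| informativeness percentile are
    excluded.
    """
    params = params or RelatednessParams()
    if marg is None:
        marg = PanelMarginals.from_matrix(profiles)

    model_genes = sorted(model.members)
    present = [g for g in model_genes if g in profiles.index]
    skipped = [g for g in model_genes if g not in profiles.index]
    if len(present) < 2:
        return ProfileRecruitment(recruits=[], skipped_model_genes=skipped)

    candidates = sorted(set(profiles.index) - set(model_genes))
    mat = profiles.to_numpy(dtype=np.int8)
    idx = {g: i for i, g in enumerate(profiles.index)}

    if params.lh_percentile > 0.0:
        freq = marg.presence_freq()
        logf, log1mf = np.log(freq), np.log(1.0 - freq)
        lh = mat @ logf + (1 - mat) @ log1mf
        cut = np.percentile(np.abs(lh), params.lh_percentile)
        candidates = [g for g in candidates if abs(lh[idx[g]]) >= cut]
    if not candidates:
        return ProfileRecruitment(recruits=[], skipped_model_genes=skipped)

    model_bits = mat[[idx[g] for g in present]]
    cand_bits = mat[[idx[g] for g in candidates]]

    mm = relatedness_matrix(model_bits, model_bits, params.alpha)
    np.fill_diagonal(mm, -np.inf)  # the bar excludes the anchor itself
    bar = mm.max(axis=0)  # per-anchor best competing model gene
    cm = relatedness_matrix(cand_bits, model_bits, params.alpha)

    recruits = []
    hit_rows, hit_cols = np.nonzero(cm > bar[None, :])
    for r, c in zip(hit_rows, hit_cols):
        recruits.append(ProfileRecruit(candidates[r], present[c],
                                       float(cm[r, c])))
    recruits.sort(key=lambda x: (x.gene, x.anchor))
    return ProfileRecruitment(recruits=recruits, skipped_model_genes=skipped)
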
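"""Scikit-learn-style estimator facades over the PWM screen.

``PDZSpecificityModel`` is fit on per-domain peptide alignments and
transforms C-terminal sequences into a matrix of log10 PWM scores;
``MotifChangeClassifier`` adds the two-threshold rule and predicts a
verdict for (wild-type, mutant) sequence pairs.  Both follow the
get_params/set_params/clone protocol and compose with sklearn
pipelines; the functional API in :mod:`pdzscan.pwm` and
:mod:`pdzscan.variants` stays the primary surface.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .pwm import PWM, PeptideAlignment, build_pwm, consensus, score_cterm
from .variants import ClassificationConfig, classify_variant


def _as_alignments(X) -> list[PeptideAlignment]:
    if isinstance(X, Mapping):
        return [PeptideAlignment(d, peps) for d, peps in X.items()]
    out = []
    for item in X:
        if isinstance(item, PeptideAlignment):
            out.append(item)
        else:
            domain_id, peptides = item
            out.append(PeptideAlignment(domain_id, peptides))
    return out


class PDZSpecificityModel(TransformerMixin, BaseEstimator):
    """PWM specificity model over a panel of PDZ domains.

    Parameters
    ----------
    kappa : float, information-content pseudocount weight (0 disables
        smoothing).
    pseudocount_mode : {"proportional", "inverse", "flat"}
    log_base : float, base of the score logarithm (10 by default; the
        working thresholds -8.3 / -6.4 assume base 10).

    Attributes
    ----------
    pwms_ : list of fitted PWM, one per domain.
    domain_ids_ : list of str.
    """

    def __init__(self, kappa: float = 1.0, pseudocount_mode: str = "proportional",
                 log_base: float = 10.0):
        self.kappa = kappa
        self.pseudocount_mode = pseudocount_mode
        self.log_base = log_base

    def fit(self, X, y=None):
        """X: iterable of PeptideAlignment, (domain_id, peptides) pairs,
        or a mapping domain_id -> peptides."""
        alignments = _as_alignments(X)
        if not alignments:
            raise ValueError("at least one peptide alignment is required")
        self.pwms_ = [
            build_pwm(a, self.kappa, self.pseudocount_mode) for a in alignments
        ]
        self.domain_ids_ = [p.domain_id for p in self.pwms_]
        self.n_domains_ = len(self.pwms_)
        return self

    def score_samples(self, X) -> np.ndarray:
        """(n_sequences, n_domains) matrix of log scores."""
        check_is_fitted(self, "pwms_")
        seqs = [s.sequence if hasattr(s, "sequence") else str(s) for s in X]
        return np.array(
            [
                [score_cterm(p, s, log_base=self.log_base) for p in self.pwms_]
                for s in seqs
            ]
        )

    def transform(self, X) -> np.ndarray:
        return self.score_samples(X)

    def consensus_sequences(self) -> list[str]:
        check_is_fitted(self, "pwms_")
        return [consensus(p) for p in self.pwms_]


class MotifChangeClassifier(BaseEstimator):
    """Two-threshold verdict for (wild-type, mutant) C-terminal pairs.

    predict(X) takes an array-like of shape (n, 2) of sequences and
    returns "disrupts", "creates" or "neutral" per pair: a pair
    disrupts when some fitted domain scores the wild type above s_max
    and the mutant below s_min (strictly); creates is the mirror.
    """

    def __init__(self, s_min: float = -8.3, s_max: float = -6.4,
                 kappa: float = 1.0, pseudocount_mode: str = "proportional"):
        self.s_min = s_min
        self.s_max = s_max
        self.kappa = kappa
        self.pseudocount_mode = pseudocount_mode

    def fit(self, X, y=None):
        self.config_ = ClassificationConfig(s_min=self.s_min, s_max=self.s_max)
        self.specificity_ = PDZSpecificityModel(
            kappa=self.kappa, pseudocount_mode=self.pseudocount_mode
        ).fit(X)
        self.classes_ = np.array(["creates", "disrupts", "neutral"])
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "specificity_")
        pairs = list(X)
        verdicts = []
        domains = self.specificity_.domain_ids_
        for wt, mut in pairs:
            wt_scores = dict(zip(domains, self.specificity_.score_samples([wt])[0]))
            mut_scores = dict(zip(domains, self.specificity_.score_samples([mut])[0]))
            verdicts.append(
                classify_variant(wt_scores, mut_scores, self.config_).verdict
            )
        return np.array(verdicts)
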
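"""The two-gene stress index and PCA-based marker selection.

Under acute heat-light stress the small heat-shock protein Hsp16 is
strongly induced while actin is repressed. Their difference on the raw
(non-normalized) Ca scale,

    D = Ca(Hsp16) - Ca(actin),

combines both dynamic ranges and needs no control genes: the per-sample
template-loading factor shifts every gene of a sample equally and
cancels in the difference. D is negative in unstressed corals and rises
toward (or above) zero under stress.

``pca_markers`` reproduces the logic that selected this gene pair:
principal components of the centered normalized-Ca matrix, with the
extreme positive and extreme negative loadings on PC1 proposed as the
two-gene assay.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .datatypes import CaMatrix, EffectEstimate
from .diffexpr import DesignSpec, InferenceConfig, fit_gene_model
from .errors import InvalidArgumentError

logger = logging.getLogger(__name__)


@dataclass
class PsiResult:
    """Per-sample stress-index values D (log2 units)."""

    values: pd.Series
    numerator: str
    denominator: str
    omitted_samples: tuple[str, ...] = ()


@dataclass
class PcaResult:
    variance_fraction: np.ndarray      # per component, sums to 1
    loadings: pd.DataFrame             # genes x components, unit-norm columns
    scores: pd.DataFrame               # samples x components
    marker_positive: str               # extreme positive PC1 loading
    marker_negative: str               # extreme negative PC1 loading

    @property
    def marker_pair(self) -> tuple[str, str]:
        return (self.marker_positive, self.marker_negative)


def compute_psi(
    raw_ca: CaMatrix,
    numerator_gene: str = "Hsp16",
    denominator_gene: str = "Actin",
) -> PsiResult:
    """D(s) = Ca(s, numerator) - Ca(s, denominator) on non-normalized Ca.

    Samples missing either gene are omitted with a warning. Normalized
    input is rejected: the index is defined on raw Ca precisely so that
    no normalization is needed.
    """
    if raw_ca.normalized:
        raise InvalidArgumentError(
            "the stress index is defined on non-normalized Ca values"
        )
    for g in (numerator_gene, denominator_gene):
        if g not in raw_ca.values.columns:
            raise InvalidArgumentError(f"gene {g!r} not in matrix")
    num = raw_ca.values[numerator_gene]
    den = raw_ca.values[denominator_gene]
    d = num - den
    omitted = tuple(d.index[d.isna()])
    if omitted:
        logger.warning(
            "%d sample(s) missing %s or %s; omitted from the index: %s",
            len(omitted), numerator_gene, denominator_gene, list(omitted),
        )
    return PsiResult(
        values=d.dropna().rename("psi"),
        numerator=numerator_gene,
        denominator=denominator_gene,
        omitted_samples=omitted,
    )


def compare_psi(
    psi: PsiResult,
    metadata: pd.DataFrame,
    design: DesignSpec,
    inference: InferenceConfig | None = None,
) -> EffectEstimate:
    """Fit the design's (mixed) model with D as the response.

    Colony enters as a random factor for paired designs, tank
    additionally for the tank experiment; the two-site field comparison
    is a plain two-group linear model. Returns the estimate of the
    single treatment/site contrast.
    """
    df = metadata.join(psi.values, how="inner")
    ests = fit_gene_model(df, design, inference, response="psi",
                          gene_id=f"{psi.numerator}-{psi.denominator}")
    primary = design.fixed[0]
    for est in ests:
        if est.term == primary or est.term.startswith(f"{primary}@") \
                or est.term.startswith(f"{primary}["):
            return est
    return ests[0]


def pca_markers(
    norm_ca: CaMatrix,
    treatments: pd.Series,
    stress_level: str | None = None,
    scale: bool = False,
) -> PcaResult:
    """Centered (optionally scaled) PCA with marker-pair selection.

    The matrix is restricted to samples without missing values. PC signs
    are indeterminate, so PC1 is oriented to score stressed samples
    higher than the rest (``stress_level`` defaults to 'heat' when
    present, else the last label in sorted order); the gene pair with the
    extreme positive and extreme negative PC1 loadings is proposed as the
    two-gene assay.
    """
    if norm_ca.values.shape[1] < 2:
        raise InvalidArgumentError("PCA needs >= 2 genes")
    X = norm_ca.values.dropna(axis=0)
    if X.shape[0] < 3:
        raise InvalidArgumentError("PCA needs >= 3 complete samples")
    if float(X.var(ddof=0).sum()) < 1e-24:
        raise InvalidArgumentError("matrix is constant; PCA undefined")
    mat = X.to_numpy(dtype=float)
    if scale:
        sd = mat.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise InvalidArgumentError("cannot scale genes with zero variance")
        mat = (mat - mat.mean(axis=0)) / sd

    pca = PCA(n_components=None)
    scores = pca.fit_transform(mat)
    loadings = pca.components_.T  # genes x components, rows of components_ unit norm

    labels = treatments.reindex(X.index)
    if labels.isna().any():
        raise InvalidArgumentError("treatment label missing for some samples")
    if stress_level is None:
        uniq = sorted(labels.unique())
        stress_level = "heat" if "heat" in uniq else uniq[-1]
    is_stress = (labels == stress_level).to_numpy()
    if is_stress.any() and (~is_stress).any():
        if scores[is_stress, 0].mean() < scores[~is_stress, 0].mean():
            scores[:, 0] *= -1.0
            loadings[:, 0] *= -1.0

    comp_names = [f"PC{i + 1}" for i in range(loadings.shape[1])]
    loadings_df = pd.DataFrame(loadings, index=X.columns, columns=comp_names)
    scores_df = pd.DataFrame(scores, index=X.index, columns=comp_names)
    pc1 = loadings_df["PC1"]
    return PcaResult(
        variance_fraction=pca.explained_variance_ratio_,
        loadings=loadings_df,
        scores=scores_df,
        marker_positive=str(pc1.idxmax()),
        marker_negative=str(pc1.idxmin()),
    )
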
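"""In-memory containers shared across the pipeline.

Genotype posteriors are held densely: for typical rare-variant panels (tens
of variants per gene, tens of thousands of samples) this is a few MB and
keeps the sampling arithmetic vectorized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GenotypeData", "ANNOTATION_COLUMNS", "PHENOTYPE_COLUMNS"]

# annotation table schema (TSV on disk)
ANNOTATION_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "variant_id",
    "gene",
    "functional_class",  # LOF | missense | other
    "lof_confidence",  # HC | LC | NA
    "revel",  # 0-100 or NaN
    "maf_internal",
    "maf_reference",
]

PHENOTYPE_COLUMNS = [
    "sample_id",
    "status",  # EOAD | LOAD | control
    "outcome",  # 0 = control < 1 = LOAD < 2 = EOAD
    "age_or_onset",
    "apoe4_dosage",
    "apoe_ascertained",
]


@dataclass
class GenotypeData:
    """Per sample x variant genotype posteriors with read support.

    posterior : (n_samples, n_variants, 3) — P(hom-ref), P(het), P(hom-alt),
        each triple summing to 1.  Entries flagged missing hold the
        no-information prior used at generation/read time.
    depth : (n_samples, n_variants) total read depth.
    allele_depths : (n_samples, n_variants, 2) — (ref reads, alt reads).
    missing : boolean mask, True where depth is below the calling threshold.
    """

    samples: np.ndarray
    variants: np.ndarray
    posterior: np.ndarray
    depth: np.ndarray
    allele_depths: np.ndarray
    missing: np.ndarray

    def __post_init__(self):
        self.samples = np.asarray(self.samples)
        self.variants = np.asarray(self.variants)
        self._vindex = {v: i for i, v in enumerate(self.variants)}
        sums = self.posterior.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("posterior triples must sum to 1")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self, variant_ids) -> np.ndarray:
        try:
            return np.array([self._vindex[v] for v in variant_ids])
        except KeyError as exc:
            raise KeyError(f"variant {exc.args[0]!r} not in genotype data")

    def expected_dosage(self, variant_ids=None) -> np.ndarray:
        """Posterior-mean alt-allele dosage, (n_samples, n_variants)."""
        post = self.posterior
        if variant_ids is not None:
            post = post[:, self.variant_index(variant_ids), :]
        return post[..., 1] + 2.0 * post[..., 2]

    def hard_calls(self, variant_ids=None) -> np.ndarray:
        """Posterior-mode genotypes; -1 where missing."""
        post = self.posterior
        miss = self.missing
        if variant_ids is not None:
            idx = self.variant_index(variant_ids)
            post = post[:, idx, :]
            miss = miss[:, idx]
        calls = post.argmax(axis=-1).astype(np.int64)
        calls[miss] = -1
        return calls


def empty_phenotypes() -> pd.DataFrame:
    return pd.DataFrame(columns=PHENOTYPE_COLUMNS)
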
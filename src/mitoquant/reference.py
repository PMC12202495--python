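"""Published group-level reference values bundled with the package.

These are the printed results of the hooded-seal / mouse visual-cortex
study the pipeline operationalizes: the curated electron-transport-chain
gene table (TPM in mouse vs. seal neurons with upstream FDR values),
group mean fractional MCT4 areas, and the fitted model summaries
(link-scale least-squares means and their pairwise contrasts) for
mitochondrial density (Poisson, log link — lsmeans are log-densities) and
mitochondrial cross-sectional size (Gamma, log link — lsmeans
back-transform to mean sizes in µm²).

They serve as worked-example inputs and internal-consistency checks:
e.g. recomputing fold changes from the TPM columns, back-transforming
size lsmeans to the reported group mean sizes, or verifying that each
printed contrast equals the difference of its two printed lsmeans.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_complex_gene_table",
    "FRACTIONAL_MCT4_AREA",
    "DENSITY_LSMEANS",
    "DENSITY_CONTRASTS",
    "SIZE_LSMEANS",
    "SIZE_CONTRASTS",
    "MEAN_SIZE_UM2",
    "RESPIROMETRY_GROUP_METRICS",
]


def load_complex_gene_table() -> pd.DataFrame:
    """Curated complex I/II gene table: TPM per group, upstream FDR, printed fold.

    ``tpm_a`` is the mouse-neuron TPM, ``tpm_b`` the seal-neuron TPM;
    ``fold_change_printed`` is the upstream engine's signed fold change
    (it differs from the raw TPM ratio by at most a few percent).
    """
    with resources.files("mitoquant.data").joinpath("complex_genes.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


#: group mean fractional MCT4 area (dimensionless) ± s.e.m., 75 cells/individual
FRACTIONAL_MCT4_AREA = {
    ("mouse", "astrocyte"): (0.270, 0.06),
    ("mouse", "neuron"): (0.013, 0.002),
    ("seal", "astrocyte"): (0.129, 0.048),
    ("seal", "neuron"): (0.097, 0.001),
}

#: mitochondrial density model: link-scale lsmeans per group:cell_type
DENSITY_LSMEANS = {
    "adult_seal:neuron": 7.67,
    "adult_seal:astrocyte": 7.89,
    "mouse:astrocyte": 7.92,
    "juv_seal:astrocyte": 8.15,
    "mouse:neuron": 8.23,
    "juv_seal:neuron": 8.47,
}

#: density model pairwise contrasts: (cell_1, cell_2, printed estimate)
DENSITY_CONTRASTS = [
    ("adult_seal:astrocyte", "adult_seal:neuron", 0.221),
    ("mouse:astrocyte", "adult_seal:neuron", 0.2569),
    ("mouse:astrocyte", "adult_seal:astrocyte", 0.0358),
    ("juv_seal:astrocyte", "adult_seal:neuron", 0.4866),
    ("juv_seal:astrocyte", "adult_seal:astrocyte", 0.2656),
    ("juv_seal:astrocyte", "mouse:astrocyte", 0.2298),
    ("mouse:neuron", "adult_seal:neuron", 0.561),
    ("mouse:neuron", "adult_seal:astrocyte", 0.34),
    ("mouse:neuron", "mouse:astrocyte", 0.3042),
    ("mouse:neuron", "juv_seal:astrocyte", 0.0744),
    ("juv_seal:neuron", "adult_seal:neuron", 0.8026),
    ("juv_seal:neuron", "adult_seal:astrocyte", 0.5816),
    ("juv_seal:neuron", "mouse:astrocyte", 0.5457),
    ("juv_seal:neuron", "juv_seal:astrocyte", 0.316),
    ("juv_seal:neuron", "mouse:neuron", 0.2416),
]

#: mitochondrial size model: link-scale lsmeans per group:cell_type
SIZE_LSMEANS = {
    "adult_seal:neuron": -0.352,
    "mouse:neuron": -0.252,
    "adult_seal:astrocyte": -0.235,
    "juv_seal:astrocyte": -0.157,
    "juv_seal:neuron": -0.154,
    "mouse:astrocyte": -0.153,
}

#: size model pairwise contrasts: (cell_1, cell_2, printed estimate)
SIZE_CONTRASTS = [
    ("mouse:neuron", "adult_seal:neuron", 0.10028),
    ("adult_seal:astrocyte", "adult_seal:neuron", 0.11697),
    ("adult_seal:astrocyte", "mouse:neuron", 0.01669),
    ("juv_seal:astrocyte", "adult_seal:neuron", 0.19495),
    ("juv_seal:astrocyte", "mouse:neuron", 0.09467),
    ("juv_seal:astrocyte", "adult_seal:astrocyte", 0.07798),
    ("juv_seal:neuron", "adult_seal:neuron", 0.19829),
    ("juv_seal:neuron", "mouse:neuron", 0.09801),
    ("juv_seal:neuron", "adult_seal:astrocyte", 0.08132),
    ("juv_seal:neuron", "juv_seal:astrocyte", 0.00333),
    ("mouse:astrocyte", "adult_seal:neuron", 0.19869),
    ("mouse:astrocyte", "mouse:neuron", 0.09841),
    ("mouse:astrocyte", "adult_seal:astrocyte", 0.08172),
    ("mouse:astrocyte", "juv_seal:astrocyte", 0.00373),
    ("mouse:astrocyte", "juv_seal:neuron", 0.0004),
]

#: reported mean mitochondrial cross-sectional sizes (µm²)
MEAN_SIZE_UM2 = {
    "adult_seal:astrocyte": 0.79,
    "juv_seal:astrocyte": 0.86,
    "mouse:astrocyte": 0.84,
    "adult_seal:neuron": 0.70,
    "juv_seal:neuron": 0.85,
    "mouse:neuron": 0.78,
}

#: reported respirometry group metrics, mean ± s.e.m. (seal primary cultures)
RESPIROMETRY_GROUP_METRICS = {
    "rel_CI": {"astrocyte": (0.645, 0.013), "neuron": (0.791, 0.042)},
    "rel_CII": {"astrocyte": (0.813, 0.019), "neuron": (0.842, 0.006)},
    "coupling_CI": {"astrocyte": (0.47, 0.036), "neuron": (0.40, 0.045)},
    "pct_change_ADP": {"astrocyte": (39.5, 6.09), "neuron": (22.8, 5.03)},
    "pct_change_succinate": {"astrocyte": (55.5, 3.26), "neuron": (27.4, 6.27)},
}
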
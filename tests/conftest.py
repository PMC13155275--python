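import numpy as np
import pandas as pd
import pytest

from ironsmoke.io import GeneAnnotation
from ironsmoke.simulate import LdBlockSpec, generate_panel
from ironsmoke import ldsc


@pytest.fixture(scope="session")
def ldsc_genome():
    """Toy genome for LD-score regression: 120 LD blocks of 20 SNPs with
    mixed AR correlations (wide LD-score spread identifies slope and
    intercept), 4000 haplotypes, plus a blank annotation."""
    rhos = list(np.tile([0.1, 0.4, 0.6, 0.8, 0.9, 0.95], 20))
    spec = LdBlockSpec([20] * 120, ar_rho=rhos)
    panel = generate_panel(4000, spec, spacing_bp=500, seed=5)
    scores = ldsc.ld_scores(panel, window_bp=12_000)
    ann = GeneAnnotation(pd.DataFrame(
        columns=["gene_id", "chrom", "start", "end", "strand"]))
    return panel, scores, ann


@pytest.fixture(scope="session")
def mr_genome():
    """Toy genome for MR and the ratio test: 40 genes, each spanning one
    AR(0.7) LD block of 15 SNPs (1-kb spacing), 1000 haplotypes."""
    nb, bs = 40, 15
    spec = LdBlockSpec([bs] * nb, ar_rho=0.7)
    panel = generate_panel(1000, spec, spacing_bp=1000, seed=9)
    starts = 1_000_000 + bs * 1000 * np.arange(nb)
    ann = GeneAnnotation(pd.DataFrame({
        "gene_id": [f"G{j:03d}" for j in range(nb)],
        "chrom": "1", "start": starts, "end": starts + (bs - 1) * 1000,
        "strand": "+",
    }))
    return panel, ann


@pytest.fixture(scope="session")
def calib_genome():
    """Null-calibration genome: many independent 10-SNP AR(0.8) blocks,
    one gene per block; shared by the coherence/ratio calibration tests."""
    n_genes = 5000
    spec = LdBlockSpec([10] * n_genes, ar_rho=0.8)
    panel = generate_panel(400, spec, spacing_bp=1000, seed=11)
    starts = 1_000_000 + 10_000 * np.arange(n_genes)
    ann = GeneAnnotation(pd.DataFrame({
        "gene_id": [f"G{j:04d}" for j in range(n_genes)],
        "chrom": "1", "start": starts, "end": starts + 9_000, "strand": "+",
    }))
    return panel, ann
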
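import numpy as np
import pandas as pd
import pytest

from tseakit import ExpressionPanel, SimConfig
from tseakit.simulate import simulate_study


@pytest.fixture
def toy_sumstats_file(tmp_path):
    """Write a small whitespace-separated summary-stats file; returns
    (path, column_map)."""

    def _write(rows, header="SNP CHR BP A1 A2 MAF BETA SE P N"):
        path = tmp_path / "gwas.tsv"
        path.write_text("\n".join([header] + rows) + "\n")
        cmap = {"snp_id": "SNP", "chrom": "CHR", "pos": "BP",
                "effect_allele": "A1", "other_allele": "A2", "maf": "MAF",
                "effect": "BETA", "se": "SE", "pvalue": "P", "n": "N"}
        return path, cmap

    return _write


@pytest.fixture
def small_panel():
    """10 genes x 6 samples, 3 tissues x 2 samples; gene g0 is shifted up in
    tissue A."""
    rng = np.random.default_rng(5)
    genes = [f"g{i}" for i in range(10)]
    samples = [f"s{i}" for i in range(6)]
    tissue = pd.Series(["A", "A", "B", "B", "C", "C"], index=samples)
    expr = pd.DataFrame(rng.uniform(1, 50, size=(10, 6)), index=genes, columns=samples)
    expr.loc["g0", ["s0", "s1"]] = 5000.0
    return ExpressionPanel("toy", expr, tissue)


@pytest.fixture(scope="session")
def planted_study():
    """One seeded synthetic study with signal in tissue_0 (shared, read-only)."""
    cfg = SimConfig(seed=11, n_genes=400, n_tissues=4, n_samples_per_tissue=30,
                    n_snps_per_gene=4, n_causal_genes=20, ld_block_rho=0.5,
                    noncentrality=5.0, n_ref_samples=300)
    ss, genes, geno, panel, truth = simulate_study(cfg)
    return {"cfg": cfg, "ss": ss, "genes": genes, "geno": geno,
            "panel": panel, "truth": truth}
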
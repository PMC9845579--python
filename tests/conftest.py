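import numpy as np
import pandas as pd
import pytest

from panomicnet.datasets import PanomicDataset, VariableMeta, class_map
from panomicnet.scoring import PenaltyConfig


def make_noise_dataset(p: int, n: int, seed: int, var_class: str = "biomarker") -> PanomicDataset:
    rng = np.random.default_rng(seed)
    vals = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"v{i}" for i in range(p)])
    meta = [VariableMeta(f"v{i}", var_class, "continuous") for i in range(p)]
    return PanomicDataset(vals, meta)


def make_chain_dataset(p: int, n: int, seed: int, coef: float = 1.0, noise: float = 0.5):
    """Linear-Gaussian chain v0 -> v1 -> ... -> v_{p-1}."""
    rng = np.random.default_rng(seed)
    cols = {}
    prev = None
    for i in range(p):
        x = rng.normal(size=n) if prev is None else coef * prev + noise * rng.normal(size=n)
        cols[f"v{i}"] = x
        prev = x
    meta = [VariableMeta(f"v{i}", "biomarker", "continuous") for i in range(p)]
    return PanomicDataset(pd.DataFrame(cols), meta)


def penalty_for(dataset: PanomicDataset, **kw) -> PenaltyConfig:
    return PenaltyConfig(class_map=class_map(dataset), **kw)


@pytest.fixture(scope="session")
def default_spec():
    from panomicnet import synthetic

    return synthetic.default_ground_truth(1)


@pytest.fixture(scope="session")
def vcf_path(tmp_path_factory):
    """A tiny plain-text VCF with two variants over three samples."""
    text = "\n".join(
        [
            "##fileformat=VCFv4.2",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            "##contig=<ID=1,length=1000000>",
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3",
            "1\t100\trs_a\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1",
            "1\t200\trs_b\tC\tT\t.\tPASS\t.\tGT\t1|0\t0|0\t1|1",
            "1\t300\trs_miss\tG\tA\t.\tPASS\t.\tGT\t./0\t0/0\t0/0",
        ]
    )
    path = tmp_path_factory.mktemp("vcf") / "variants.vcf"
    path.write_text(text + "\n")
    return path
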
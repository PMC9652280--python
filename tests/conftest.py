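"""Shared fixtures: a small synthetic two-strain dataset generated once."""

from __future__ import annotations

import pytest

from kstrain.pipeline import RunConfig, SampleSpec
from kstrain.simulate import SimulationConfig, VariantSpec, simulate_dataset


@pytest.fixture(scope="session")
def make_run_config():
    """Factory building a RunConfig from a simulate_dataset() result."""

    def _make(data, outdir, **overrides) -> RunConfig:
        strains = {
            strain: [SampleSpec(sample_id=s["sample_id"], fastq=[str(s["fastq"])],
                                sex=s["sex"])
                     for s in info["samples"]]
            for strain, info in data["strains"].items()
        }
        kwargs = dict(
            reference=str(data["reference_path"]),
            gff3=str(data["gff3_path"]),
            outdir=str(outdir),
            strains=strains,
            min_individuals={s: 3 for s in strains},
        )
        kwargs.update(overrides)
        return RunConfig(**kwargs)

    return _make


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A 30 kb two-strain study: strain A carries planted variants, strain B
    is reference-identical; 4 error-free individuals per strain at 25x."""
    outdir = tmp_path_factory.mktemp("dataset")
    config = SimulationConfig(
        reference_length=30_000,
        n_individuals_a=4,
        n_individuals_b=4,
        coverage=25.0,
        read_length=100,
        error_rate=0.0,
        seed=11,
        variants_a=VariantSpec(12, 3, 3, min_spacing=54),
        variants_b=VariantSpec(0, 0, 0),
        n_genes=6,
    )
    data = simulate_dataset(config, outdir)
    data["config"] = config
    data["outdir"] = outdir
    return data
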
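import random

import pytest

from fedprot.fixtures import generate_corpus
from fedprot.report import run_build


@pytest.fixture(scope="session")
def corpus(tmp_path_factory):
    """Default synthetic corpus: 5 families x 3 variants, 20% fragments,
    3 studies, noise-free detection, seed 7."""
    outdir = tmp_path_factory.mktemp("corpus")
    records, metas, truth = generate_corpus(outdir, seed=7)
    return outdir, records, metas, truth


@pytest.fixture(scope="session")
def corpus_config(corpus):
    outdir, _, metas, _ = corpus
    return {
        "library": {"fasta": [str(outdir / "library.fasta")]},
        "studies": [
            {"study_id": m.study_id, "format": m.format_name,
             "path": str(outdir / f"{m.study_id}.tsv")}
            for m in metas
        ],
        "annotations": str(outdir / "annotations.tsv"),
        "seed": 7,
    }


@pytest.fixture(scope="session")
def built(corpus_config):
    """Full pipeline run on the default corpus."""
    report, store = run_build(corpus_config)
    return report, store


@pytest.fixture()
def rng():
    return random.Random(20260928)
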
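import numpy as np
import pytest

from itraqpipe.reporter import PeptideQuantRecord

CONDITIONS = ("vehicle", "CsA", "Tac", "CAI")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_quant_records(
    rng,
    n,
    n_experiments=5,
    conditions=CONDITIONS,
    n_peptides=30,
    n_accessions=12,
    null_ratio_rate=0.1,
    decoy_rate=0.1,
):
    """Random peptide records with realistic messiness.

    Scores straddle the cutoff, a fraction of ratios is null, a fraction of
    records carries decoy flags, and peptides/accessions are drawn from
    small pools so the same pair recurs across experiments.
    """
    records = []
    peptides = [f"PEPTIDE{i:03d}K" for i in range(n_peptides)]
    accessions = [f"ACC{i:03d}" for i in range(n_accessions)]
    pairs = [(p, accessions[i % n_accessions]) for i, p in enumerate(peptides)]
    for _ in range(n):
        peptide, accession = pairs[rng.integers(len(pairs))]
        ratios = {}
        for cond in conditions:
            if rng.random() < null_ratio_rate:
                ratios[cond] = None
            else:
                ratios[cond] = 1.0 if cond == conditions[0] else float(
                    np.exp(rng.normal(0.0, 0.3))
                )
        flags = frozenset()
        if rng.random() < decoy_rate:
            flags = frozenset({"REVERSED" if rng.random() < 0.5 else "Fragment"})
        records.append(
            PeptideQuantRecord(
                peptide_sequence=peptide,
                accession=accession,
                flags=flags,
                score=float(rng.uniform(0.0, 80.0)),
                ratios=ratios,
                experiment_id=f"exp{int(rng.integers(1, n_experiments + 1))}",
            )
        )
    return records
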
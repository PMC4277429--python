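import numpy as np
import pandas as pd
import pytest

from exondiff.count_io import ExonCountTable


@pytest.fixture
def small_table() -> ExonCountTable:
    """Two genes (3 + 2 exons), four samples in two groups."""
    exon_ids = ["G1:E001", "G1:E002", "G1:E003", "G2:E001", "G2:E002"]
    counts = pd.DataFrame(
        {
            "a1": [5, 7, 2, 40, 10],
            "a2": [6, 8, 1, 38, 12],
            "b1": [15, 20, 2, 42, 11],
            "b2": [14, 22, 3, 39, 9],
        },
        index=pd.Index(exon_ids),
    )
    gene_of = pd.Series([e.split(":")[0] for e in exon_ids], index=counts.index)
    groups = pd.Series({"a1": "g1", "a2": "g1", "b1": "g2", "b2": "g2"})
    return ExonCountTable(counts=counts, gene_of=gene_of, groups=groups)


@pytest.fixture
def dexseq_dir(tmp_path):
    """Two single-sample count files in the two-column dialect plus a sheet."""
    lines_a = ["G1:E001\t5", "G1:E002\t7", "_ambiguous\t3"]
    lines_b = ["G1:E001\t9", "G1:E002\t1", "_no_feature\t8"]
    (tmp_path / "sampleA.txt").write_text("\n".join(lines_a) + "\n")
    (tmp_path / "sampleB.txt").write_text("\n".join(lines_b) + "\n")
    sheet = pd.DataFrame(
        {
            "sample_id": ["A", "B"],
            "group": ["g1", "g2"],
            "file_path": [str(tmp_path / "sampleA.txt"), str(tmp_path / "sampleB.txt")],
        }
    )
    sheet_path = tmp_path / "samples.tsv"
    sheet.to_csv(sheet_path, sep="\t", index=False)
    return tmp_path, sheet_path
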
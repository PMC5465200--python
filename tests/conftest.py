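import pytest

from ystr.data_io import StrHaplotype

#: A realistic Central Asian 15-locus profile used as a test base.
BASE_ALLELES = (14, 17, 25, 15, 16, 17, 14, 10, 20, 10, 10, 11, 13, 11, 23)


@pytest.fixture
def hap():
    """Factory for 15-locus haplotypes with targeted allele changes."""

    def make(changes=(), haplogroup="C2b1a2-M48", dup=False,
             base=BASE_ALLELES):
        alleles = list(base)
        for idx, value in changes:
            alleles[idx] = value
        return StrHaplotype(
            alleles=tuple(alleles), haplogroup=haplogroup,
            dys19_duplicated=dup,
        )

    return make


@pytest.fixture
def sample_table(tmp_path):
    """Write a TSV sample table from a list of header/rows and return path."""

    def write(header, rows, name="samples.tsv"):
        path = tmp_path / name
        lines = ["\t".join(header)]
        lines += ["\t".join(str(c) for c in row) for row in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    return write
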
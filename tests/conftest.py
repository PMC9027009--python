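import numpy as np
import pytest

from sexmark.datamodel_io import (
    ABSENT,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    PRESENCE_UNKNOWN,
    PRESENT,
    Dataset,
    Individual,
    Sex,
    SiteGenotypes,
    TagLocus,
)

# short aliases used throughout the suite
RR, RA, AA, NN = HOM_REF, HET, HOM_ALT, MISSING
P, A, U = PRESENT, ABSENT, PRESENCE_UNKNOWN


def individuals_for(n_females: int, n_males: int, n_unknown: int = 0) -> list[Individual]:
    return (
        [Individual(f"F{i}", Sex.FEMALE) for i in range(n_females)]
        + [Individual(f"M{i}", Sex.MALE) for i in range(n_males)]
        + [Individual(f"U{i}", Sex.UNKNOWN) for i in range(n_unknown)]
    )


def site_dataset(f_calls, m_calls, u_calls=(), tag_id="t1", site_index=0) -> Dataset:
    """One-tag, one-site dataset: females first, then males, then unknowns."""
    inds = individuals_for(len(f_calls), len(m_calls), len(u_calls))
    calls = np.array(list(f_calls) + list(m_calls) + list(u_calls), dtype=np.int8)
    site = SiteGenotypes(tag_id, site_index, "A", "G", calls)
    return Dataset(inds, [TagLocus(tag_id, sites=[site])])


def presence_dataset(f_pres, m_pres, u_pres=(), tag_id="t1") -> Dataset:
    inds = individuals_for(len(f_pres), len(m_pres), len(u_pres))
    pres = np.array(list(f_pres) + list(m_pres) + list(u_pres), dtype=np.int8)
    return Dataset(inds, [TagLocus(tag_id, presence=pres)])


@pytest.fixture
def toy_table(tmp_path):
    """2-tag, 4-sample genotype table + sex map (as in the shape contract)."""
    table = tmp_path / "geno.tsv"
    table.write_text(
        "tag_id\tsite\tref\talt\ts1\ts2\ts3\ts4\n"
        "tagA\t10\tA\tG\t0/0\t0/1\t1/1\t./.\n"
        "tagA\t25\tC\tT\t0/1\t0/1\t0/0\t0/0\n"
        "tagB\t3\tG\tA\t1/1\t1/1\t0/1\t0/1\n"
    )
    sexmap = tmp_path / "sex.tsv"
    sexmap.write_text("s1\tF\ns2\tF\ns3\tM\ns4\tM\n")
    return table, sexmap
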
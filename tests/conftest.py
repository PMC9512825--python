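import numpy as np
import pandas as pd
import pytest

from breakclust.simulate import Driver, SimConfig, simulate


def small_config(seed=0, drivers="default"):
    """A reduced cohort for pipeline-level tests: 8 chromosomes, 60 donors.

    Keeps every chromosome above the 100-breakpoint modeling minimum
    while running in a couple of seconds.
    """
    cl = {f"chr{i}": 25_000_000 for i in range(1, 9)}
    if drivers == "default":
        # higher prevalence than the full-size conditions: 60 donors give
        # proportionally smaller clusters, so recovery tests stay sharp
        drv = [Driver("chr2", 8_950_000, 9_050_000, prevalence=0.5),
               Driver("chr5", 15_950_000, 16_050_000, prevalence=0.5)]
    else:
        drv = drivers
    return SimConfig(seed=seed, n_donors=60, chrom_lengths=cl,
                     mean_svs_per_donor=25.0, drivers=drv)


@pytest.fixture(scope="session")
def small_sim():
    cfg = small_config(seed=7)
    sv, ann = simulate(cfg)
    return cfg, sv, ann


@pytest.fixture(scope="session")
def sv_table_file(tmp_path_factory, small_sim):
    from breakclust.simulate import write_annotations, write_sv_table
    cfg, sv, ann = small_sim
    d = tmp_path_factory.mktemp("simdata")
    write_sv_table(sv, d / "sv_table.tsv")
    write_annotations(ann, d / "annotations")
    return d


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_sv_rows(rows):
    """Build an on-disk-format SV table (1-based) from terse tuples:
    (donor, type, sv, chrom1, pos1, chrom2, pos2)."""
    recs = []
    for donor, typ, svid, c1, p1, c2, p2 in rows:
        recs.append(["COH", donor, typ, svid, c1, p1, p1, "+",
                     c2, p2, p2, "-"])
    cols = ["cohort_code", "donor_id", "variant_type", "sv_id",
            "chr_from", "chr_from_bkpt_start", "chr_from_bkpt_end",
            "chr_from_strand", "chr_to", "chr_to_bkpt_start",
            "chr_to_bkpt_end", "chr_to_strand"]
    return pd.DataFrame(recs, columns=cols)
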
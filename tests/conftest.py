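import pytest

from allodriver.driver_model import EnsembleConfig, SmoteConfig, save_model, train
from allodriver.formats_io import load_fasta
from allodriver.site_db import load_site_db
from allodriver.synthetic_fixtures import (
    FixtureSpec,
    SeparationSpec,
    gen_cohort_maf,
    gen_labeled_dataset,
    gen_site_world,
)

WORLD_SPEC = FixtureSpec(
    n_proteins=4,
    sites_per_protein=3,
    seq_length=90,
    n_samples=3,
    muts_per_sample=8,
    frac_on_sites=0.5,
    seed=11,
)


@pytest.fixture(scope="session")
def world(tmp_path_factory):
    return gen_site_world(WORLD_SPEC, tmp_path_factory.mktemp("world"))


@pytest.fixture(scope="session")
def cohort_maf(world, tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort") / "cohort.maf"
    return gen_cohort_maf(WORLD_SPEC, world, out)


@pytest.fixture(scope="session")
def db_functional(world):
    return load_site_db(world.sites_path, world.residues_path, world.genemap_path, "FUNCTIONAL")


@pytest.fixture(scope="session")
def db_allosteric(world):
    return load_site_db(world.sites_path, world.residues_path, world.genemap_path, "ALLOSTERIC")


@pytest.fixture(scope="session")
def seqs(world):
    return load_fasta(world.fasta_path)


@pytest.fixture(scope="session")
def trained_model():
    """Small but real ensemble, trained once per session on separable data."""
    ds = gen_labeled_dataset(SeparationSpec(n_pos=24, n_neg=197, dprime=2.5, seed=5))
    return train(ds, EnsembleConfig(seed=5), SmoteConfig(seed=5))


@pytest.fixture(scope="session")
def model_path(trained_model, tmp_path_factory):
    path = tmp_path_factory.mktemp("model") / "model.joblib"
    save_model(trained_model, path)
    return path


def write_world(directory, proteins, site_rows, rsa=0.5, flex=0.0):
    """Hand-built world: proteins = {uid: (gene, seq)}, site_rows = list of
    (uid, site_id, site_type, residues-iterable).  Residue annotations cover
    every position with constant rsa/flex."""
    directory.mkdir(parents=True, exist_ok=True)
    sites = ["uniprot_id\tgene_symbol\tpdb_id\tsite_id\tsite_type\tresidues"]
    for uid, site_id, stype, residues in site_rows:
        gene = proteins[uid][0]
        sites.append(
            f"{uid}\t{gene}\t1XYZ\t{site_id}\t{stype}\t" + ",".join(map(str, residues))
        )
    res = ["uniprot_id\tposition\twt_aa\trsa\tflex"]
    fasta = []
    gm = ["gene_symbol\tuniprot_id"]
    for uid, (gene, seq) in proteins.items():
        gm.append(f"{gene}\t{uid}")
        fasta.append(f">sp|{uid}|{gene}_TEST synthetic")
        fasta.append(seq)
        for pos, aa in enumerate(seq, start=1):
            res.append(f"{uid}\t{pos}\t{aa}\t{rsa}\t{flex}")
    (directory / "sites.tsv").write_text("\n".join(sites) + "\n")
    (directory / "residues.tsv").write_text("\n".join(res) + "\n")
    (directory / "gene_map.tsv").write_text("\n".join(gm) + "\n")
    (directory / "proteins.fasta").write_text("\n".join(fasta) + "\n")
    return directory


def repeat_seq(length, period="ACDEFGHIKLMNPQRSTVWY"):
    reps = length // len(period) + 1
    return (period * reps)[:length]
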
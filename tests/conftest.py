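import pandas as pd
import pytest

from ibdgba.io import read_hgnc_table
from ibdgba.simulate import CatalogSimConfig, TpmSimConfig, generate_catalog, generate_tpm_matrix

CATALOG_HEADER = [
    "PUBMEDID", "FIRST AUTHOR", "DISEASE/TRAIT", "MAPPED_TRAIT_URI", "SNPS",
    "CHR_ID", "CHR_POS", "MAPPED_GENE", "SNP_GENE_IDS", "P-VALUE",
]


def make_catalog_file(path, rows):
    """Write a GWAS Catalog-dialect TSV from a list of row dicts."""
    df = pd.DataFrame(rows, columns=CATALOG_HEADER).fillna("")
    df.to_csv(path, sep="\t", index=False)
    return str(path)


def catalog_row(**kw):
    row = {
        "PUBMEDID": "30000001",
        "FIRST AUTHOR": "Author00",
        "DISEASE/TRAIT": "Ulcerative colitis",
        "MAPPED_TRAIT_URI": "http://www.ebi.ac.uk/efo/EFO_0000729",
        "SNPS": "rs1000001",
        "CHR_ID": "1",
        "CHR_POS": "67240275",
        "MAPPED_GENE": "IL23R",
        "SNP_GENE_IDS": "",
        "P-VALUE": "1E-9",
    }
    row.update(kw)
    return row


@pytest.fixture(scope="session")
def hgnc_map(tmp_path_factory):
    path = tmp_path_factory.mktemp("hgnc") / "hgnc.tsv"
    df = pd.DataFrame(
        [
            {"symbol": "IL23R", "alias_symbol": "", "prev_symbol": "", "ensembl_gene_id": "ENSG00000162594"},
            {"symbol": "C1orf141", "alias_symbol": "C1orf141-OLD", "prev_symbol": "", "ensembl_gene_id": "ENSG00000203963"},
            {"symbol": "NOD2", "alias_symbol": "CARD15|IBD1", "prev_symbol": "", "ensembl_gene_id": "ENSG00000167207"},
            {"symbol": "IRF1-AS1", "alias_symbol": "", "prev_symbol": "", "ensembl_gene_id": "ENSG00000197536"},
        ]
    )
    df.to_csv(path, sep="\t", index=False)
    return read_hgnc_table(path)


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """Default synthetic catalog bundle (seed 1) shared across tests."""
    d = tmp_path_factory.mktemp("sim")
    config = CatalogSimConfig.default(seed=1)
    bundle = generate_catalog(config, d)
    return config, bundle


@pytest.fixture(scope="session")
def sim_tpm():
    """Default synthetic TPM matrix (seed 1), in memory."""
    return generate_tpm_matrix(TpmSimConfig(seed=1))
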
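import io

import pytest

from treeharvest.taxonomy import load_taxonomy

# Toy taxonomy in the single-file TSV dialect (taxon_id, name, rank, parent_id).
# "Aves" is class-level and deliberately outside the four indexed ranks; Mya is
# planted at two taxon ids so homonym-aware lookup and ambiguity flags fire.
TOY_TSV = """\
1\tAves\tclass\t0
2\tColumbiformes\torder\t1
3\tColumbidae\tfamily\t2
4\tLeptotila\tgenus\t3
5\tLeptotila verreauxi\tspecies\t4
6\tMya\tgenus\t0
7\tMya\tgenus\t0
8\tColumba\tgenus\t3
9\tColumba livia\tspecies\t8
10\tHomo\tgenus\t0
11\tHomo sapiens\tspecies\t10
12\tHomo neanderthalensis\tspecies\t10
13\tPan\tgenus\t0
14\tPan troglodytes\tspecies\t13
"""


@pytest.fixture(scope="session")
def toy_index():
    return load_taxonomy(io.StringIO(TOY_TSV))
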
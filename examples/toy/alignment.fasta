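>Amphimedon_g1
GGRVKVLFSNFVSLIVEGAHKAYEVDAKGALANLQILRFQLALDQFWIIMTESGLSLFFAADSDADKWEGHMAIGFEVCTVFLEIAALIPALIKTLIIKDLMDVPFELQAAKTNFQADMLLTKIYDPEDERVGNNADQKV
>Amphimedon_g2
GGRVKVVFSNFVSLIVEGAHKAYEVDVKGANNNLQILRFQLALDQFWIIMTESGLSLFFAADSDADKWDGWMSIGFEVCTVFLEVAALIPALIKPLIIKDLMDVPVETQAAKTNFQADMLLTKIYDREDERVGNNADQKV
>Nematostella_g3
AGRFKIVFFNFVSLIVEGAHKAYEVDAKGALANLHILRFQLALDQYWIMMTESGLPLFFASDADADKWEGHMSVGFEACTVFLEIAALIPALIKPLLIKDLMDIPIERQAAKTNFQADMLLIEIYDPEDERVGNTADEKV
>Amphimedon_g4
GDGFKVISANFTGLIVEGAQKIYEVDADGAMANLQILRYQLALDEWWIMMTESGLPVYFAADSDADKWEGQMSLGFEACTVFLEVAALILALIKSLLVKNLMDVPVTVQEAHTDFQADMLLIQVYDPEDERVGDAVDQNV
>Nematostella_g5
GEGFSVISCNYHGLIVEGAGKVYEIDRDGGMVNLQIIRYQLAIDEFWIMKTESGLPLFFASDSDAEKWDGHMSLGFEACTVFLEVAALITALINPLIIKHLMELPVQVQAAMTDFQADMLFIQVYDPEDERVGNAADQNV
>Drosophila_g6
AAGFKVVLDNFTGLIVDGARKVTEVDANGHMANLQILRIQAALDEYWIMMTESGLPFYFAINQDADKWAGSMSLGFEACTVFLEVAALITALIRPLLIKNQMDIPVKVQAAKTNFQADMLLIQIYDPEDERVGNEADQKV
>Danio_g7
GGGFRRIFQNFTGLIVEGASKVYEADSNGKSNNLQILQAQIAADEYWIILTEAGINLLFAPNDDADKWRGHMIQGFESCTFFLEVAAIIVQRIKPLSIKELMDVPVEIQAALMSFQAEMFLVQIFDPQDERVDNEADQNV
>Homo_g8
GNGFKVIFANFTGLIVEGAIKVYEVDSIGASNNLQILKTQIGANEFWIIMTEAGLPLIFAANEDADKWVGHMSAGFESCTLFLAIAALITALIKPLLIKQLMDVSVEIQAAQMNFQAKMARIQVFDPQDERVNNLADSKV
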
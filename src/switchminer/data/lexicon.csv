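brand,generic,class,aliases
Tecfidera,dimethyl fumarate,ORAL,tecfedera|tecfidara
Gilenya,fingolimod,ORAL,gilenia|gillenya
Aubagio,teriflunomide,ORAL,aubaggio|abaugio
Betaseron,interferon beta-1b,INJECTABLE,betaserone|betaseran
Rebif,interferon beta-1a,INJECTABLE,rebiff|rebiv
Avonex,interferon beta-1a,INJECTABLE,avonnex|avonix
Copaxone,glatiramer acetate,INJECTABLE,copaxon|copaxione
Extavia,interferon beta-1b,INJECTABLE,extavea|extaiva
Tysabri,natalizumab,IV,tysabry|tisabri
Novantrone,mitoxantrone,IV,novantron|novanthrone
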
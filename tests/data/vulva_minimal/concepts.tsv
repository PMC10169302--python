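id	fsn	preferred_term	fully_defined	active
root	Clinical finding (finding)	Clinical finding	0	1
nv	Neoplasm of vulva (disorder)	Neoplasm of vulva	1	1
db	Disorder of Bartholin's gland (disorder)	Disorder of Bartholin's gland	1	1
bnv	Benign neoplasm of vulva (disorder)	Benign neoplasm of vulva	1	1
mtv	Malignant tumor of vulva (disorder)	Malignant tumor of vulva	1	1
bnb	Benign neoplasm of Bartholin's gland (disorder)	Benign neoplasm of Bartholin's gland	1	1
mnb	Malignant neoplasm of greater vestibular (Bartholin's) gland (disorder)	Malignant neoplasm of greater vestibular (Bartholin's) gland	1	1
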
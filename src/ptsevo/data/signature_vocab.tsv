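# Controlled vocabulary mapping domain signature accessions to pipeline tokens.
# kind=pts rows carry (subunit, family); kind=marker rows carry a marker type.
# Editable: add rows for additional annotation sources (InterPro, TIGRFAM, ...).
# signature_id	label	kind	subunit	family	marker
PF03610	PTS_IIA_FRU_MAN_SOR	pts	IIA	FRU_MAN_SOR	-
PF03830	PTS_IIB_FRU_MAN_SOR	pts	IIB	FRU_MAN_SOR	-
PF03609	PTS_IIC_FRU_MAN_SOR	pts	IIC	FRU_MAN_SOR	-
PF03613	PTS_IID_FRU_MAN_SOR	pts	IID	FRU_MAN_SOR	-
IPR004701	PTS_IIA_FRU_MAN_SOR	pts	IIA	FRU_MAN_SOR	-
IPR004720	PTS_IIB_FRU_MAN_SOR	pts	IIB	FRU_MAN_SOR	-
IPR004700	PTS_IIC_FRU_MAN_SOR	pts	IIC	FRU_MAN_SOR	-
IPR004704	PTS_IID_FRU_MAN_SOR	pts	IID	FRU_MAN_SOR	-
PF00359	PTS_IIA_FRU_MANNITOL	pts	IIA	FRU_MANNITOL	-
PF02302	PTS_IIB_FRU_MANNITOL	pts	IIB	FRU_MANNITOL	-
PF02366	PTS_IIC_FRU_MANNITOL	pts	IIC	FRU_MANNITOL	-
PF00358	PTS_IIA_GLUCOSE	pts	IIA	GLUCOSE	-
PF00367	PTS_IIB_GLUCOSE	pts	IIB	GLUCOSE	-
PF02378	PTS_IIC_GLUCOSE	pts	IIC	GLUCOSE	-
PF02255	PTS_IIA_LACTOSE	pts	IIA	LACTOSE	-
PF02256	PTS_IIB_LACTOSE	pts	IIB	LACTOSE	-
PF02361	PTS_IIC_LACTOSE	pts	IIC	LACTOSE	-
PF03612	PTS_IIA_GLUCITOL	pts	IIA	GLUCITOL	-
PF03611	PTS_IIB_GLUCITOL	pts	IIB	GLUCITOL	-
PF03608	PTS_IIC_GLUCITOL	pts	IIC	GLUCITOL	-
PF07663	PTS_IIA_GALACTITOL	pts	IIA	GALACTITOL	-
PF03830b	PTS_IIB_GALACTITOL	pts	IIB	GALACTITOL	-
PF03926	PTS_IIC_GALACTITOL	pts	IIC	GALACTITOL	-
PF08676	PTS_IIA_ASCORBATE	pts	IIA	ASCORBATE	-
PF04290	PTS_IIB_ASCORBATE	pts	IIB	ASCORBATE	-
PF03611b	PTS_IIC_ASCORBATE	pts	IIC	ASCORBATE	-
PF00309	SIGMA54	marker	-	-	sigma54
PF04552	SIGMA54	marker	-	-	sigma54
PF04963	SIGMA54	marker	-	-	sigma54
PF01380	SIS	marker	-	-	sis
PF13580	SIS	marker	-	-	sis
PF01527	TRANSPOSASE	marker	-	-	is_element
PF13701	TRANSPOSASE	marker	-	-	is_element
PF01609	TRANSPOSASE	marker	-	-	is_element
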
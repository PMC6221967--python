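gene_symbol	universal_name	legacy_names	subunit
Rpl3	uL3	60S ribosomal protein L3	large
Rpl4	uL4	60S ribosomal protein L4	large
Rpl5	uL18	60S ribosomal protein L5	large
Rpl6	eL6	60S ribosomal protein L6	large
Rpl7	uL30	60S ribosomal protein L7	large
Rpl7a	eL8	60S ribosomal protein L7a	large
Rpl8	uL2	60S ribosomal protein L8	large
Rpl9	uL6	60S ribosomal protein L9	large
Rpl10	uL16	60S ribosomal protein L10	large
Rpl10a	uL1	60S ribosomal protein L10a	large
Rpl11	uL5	60S ribosomal protein L11	large
Rpl12	uL11	60S ribosomal protein L12	large
Rpl13	eL13	60S ribosomal protein L13	large
Rpl13a	uL13	60S ribosomal protein L13a	large
Rpl14	eL14	60S ribosomal protein L14	large
Rpl15	eL15	60S ribosomal protein L15	large
Rpl17	uL22	60S ribosomal protein L17	large
Rpl18	eL18	60S ribosomal protein L18	large
Rpl18a	eL20	60S ribosomal protein L18a	large
Rpl19	eL19	60S ribosomal protein L19	large
Rpl21	eL21	60S ribosomal protein L21	large
Rpl22	eL22	60S ribosomal protein L22	large
Rpl23	uL14	60S ribosomal protein L23	large
Rpl23a	uL23	60S ribosomal protein L23a	large
Rpl24	eL24	60S ribosomal protein L24	large
Rpl26	uL24	60S ribosomal protein L26	large
Rpl27	eL27	60S ribosomal protein L27	large
Rpl27a	uL15	60S ribosomal protein L27a	large
Rpl28	eL28	60S ribosomal protein L28	large
Rpl29	eL29	60S ribosomal protein L29	large
Rpl30	eL30	60S ribosomal protein L30	large
Rpl31	eL31	60S ribosomal protein L31	large
Rpl32	eL32	60S ribosomal protein L32	large
Rpl34	eL34	60S ribosomal protein L34	large
Rpl35	uL29	60S ribosomal protein L35	large
Rpl35a	eL33	60S ribosomal protein L35a	large
Rpl36	eL36	60S ribosomal protein L36	large
Rpl36a	eL42	60S ribosomal protein L36a	large
Rpl37	eL37	60S ribosomal protein L37	large
Rpl37a	eL43	60S ribosomal protein L37a	large
Rpl38	eL38	60S ribosomal protein L38	large
Rpl39	eL39	60S ribosomal protein L39	large
Uba52	eL40	60S ribosomal protein L40;Ubiquitin-60S ribosomal protein L40	large
Rpl41	eL41	60S ribosomal protein L41	large
Rplp0	uL10	60S acidic ribosomal protein P0	large
Rplp1	P1	60S acidic ribosomal protein P1	large
Rplp2	P2	60S acidic ribosomal protein P2	large
Rpsa	uS2	40S ribosomal protein SA;Laminin receptor 1	small
Rps2	uS5	40S ribosomal protein S2	small
Rps3	uS3	40S ribosomal protein S3	small
Rps3a	eS1	40S ribosomal protein S3a	small
Rps4x	eS4	40S ribosomal protein S4;40S ribosomal protein S4, X isoform	small
Rps5	uS7	40S ribosomal protein S5	small
Rps6	eS6	40S ribosomal protein S6	small
Rps7	eS7	40S ribosomal protein S7	small
Rps8	eS8	40S ribosomal protein S8	small
Rps9	uS4	40S ribosomal protein S9	small
Rps10	eS10	40S ribosomal protein S10	small
Rps11	uS17	40S ribosomal protein S11	small
Rps12	eS12	40S ribosomal protein S12	small
Rps13	uS15	40S ribosomal protein S13	small
Rps14	uS11	40S ribosomal protein S14	small
Rps15	uS19	40S ribosomal protein S15	small
Rps15a	uS8	40S ribosomal protein S15a	small
Rps16	uS9	40S ribosomal protein S16	small
Rps17	eS17	40S ribosomal protein S17	small
Rps18	uS13	40S ribosomal protein S18	small
Rps19	eS19	40S ribosomal protein S19	small
Rps20	uS10	40S ribosomal protein S20	small
Rps21	eS21	40S ribosomal protein S21	small
Rps23	uS12	40S ribosomal protein S23	small
Rps24	eS24	40S ribosomal protein S24	small
Rps25	eS25	40S ribosomal protein S25	small
Rps26	eS26	40S ribosomal protein S26	small
Rps27	eS27	40S ribosomal protein S27	small
Rps27a	eS31	40S ribosomal protein S27a;Ubiquitin-40S ribosomal protein S27a	small
Rps28	eS28	40S ribosomal protein S28	small
Rps29	uS14	40S ribosomal protein S29	small
Fau	eS30	40S ribosomal protein S30;Ubiquitin-like protein FUBI	small
Rack1	RACK1	Receptor of activated protein C kinase 1;40S ribosomal protein RACK1;Guanine nucleotide-binding protein subunit beta-2-like 1	small
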
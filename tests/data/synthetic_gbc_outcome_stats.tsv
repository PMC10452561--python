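variant	effect_allele	other_allele	eaf	beta	se	p	n
rs100000	A	T	0.6501831049456086	-0.008226873287402476	0.03746617962623711	0.8261972385622673	824
rs100007	C	T	0.3653055547412203	0.024002666438929905	0.03736843854731406	0.5206624606054215	824
rs100014	C	G	0.550536232794815	0.006843153513399674	0.036978269574976116	0.853182930653093	824
rs100021	T	C	0.4758912790167454	-0.04061859983291617	0.03751570524513468	0.27893751184244275	824
rs100028	A	T	0.5031330136791168	-0.00438548652516541	0.03688760471886462	0.9053642398176392	824
rs100035	C	T	0.16722138990107357	-0.051144912221620244	0.038170954363919624	0.18028083556161267	824
rs100042	C	G	0.3053405669973442	-0.03797630834719038	0.04180912223758186	0.36370606551857954	824
rs100049	T	C	0.6661701784651823	-0.01833963617489093	0.0361224710650978	0.6116587462316849	824
rs100056	A	G	0.5882080813273571	-0.002306741910921193	0.036890691016239256	0.9501414844377183	824
rs100063	C	T	0.8571298630958096	-0.007023461027389235	0.03881886337018007	0.8564232472107629	824
rs100070	A	G	0.4373014358958013	0.0013449339772905302	0.0394694287057308	0.9728170774467139	824
rs100077	T	C	0.9171204788461405	-0.04539390653125082	0.04121941710752293	0.2707770627217003	824
rs100084	G	A	0.46226830239328676	-0.03605151537445344	0.03751753191462536	0.33659013400272864	824
rs100091	C	T	0.10989857002491618	0.007991287391359455	0.034917661600597893	0.8189770328323861	824
rs100098	A	G	0.3650997266909962	-0.06192242655835013	0.03169005028281772	0.050700962282637055	824
rs100105	T	C	0.8465766655787685	0.08912148109686784	0.031889998819748654	0.0051955448096191875	824
rs100112	G	A	0.5477655417054154	0.01279136858251532	0.039188261891531496	0.7441155621277489	824
rs100119	C	T	0.2272871939763001	0.05288034389966043	0.03993318090690135	0.1854297653025766	824
rs100126	A	G	0.5984139133368986	-2.7804260104891815e-05	0.03352860774213633	0.9993383385468857	824
rs100133	T	C	0.5876642422580214	-0.07310186925340495	0.031999372895504134	0.022343443340833276	824
rs100140	G	A	0.4216369293839648	-0.031043545935042764	0.04180040912659416	0.4576867690551468	824
rs100147	C	T	0.7469186589751132	0.01411182754775624	0.03766360061557491	0.70789788227016	824
rs100154	G	A	0.7429638874185596	0.021983994930850317	0.034061829810837364	0.5186586839748158	824
rs100161	T	C	0.14090739985655298	-0.007519851676414183	0.04038337846874737	0.852278863332014	824
rs100168	A	G	0.5623422582360104	-0.02925098788183835	0.03213882290166921	0.3627460631475071	824
rs100175	C	T	0.5098354174473398	0.04116612770696727	0.039101859208683296	0.29243629540290283	824
rs100182	G	A	0.6113249670500122	0.010242254818944254	0.03308959459969799	0.7569176457875977	824
rs100189	T	C	0.9063857826686518	0.01761794156885909	0.033770955528756065	0.6018867703090156	824
rs100196	A	G	0.6994511261770067	-0.028115372563126767	0.03564578142837184	0.4302620337435663	824
rs100203	C	T	0.7990519418379287	-0.004261387335645067	0.03984649537363267	0.9148325356331921	824
rs100210	G	A	0.653233848977644	0.030418027598080852	0.0409315749692033	0.4573948987704288	824
rs100217	T	C	0.6111432817186256	-0.0036661183181420053	0.03835829691582394	0.9238576225781521	824
rs100224	A	G	0.7254601977137064	0.0024905741082368897	0.041315565577830254	0.9519312462881843	824
rs100231	C	T	0.42029649539217784	-0.03172570160142833	0.03554205434029761	0.37205839812239916	824
rs100238	G	A	0.453469537607243	0.008441058303626433	0.03375867203014262	0.8025555002010649	824
rs100245	T	C	0.2096774590481626	0.001979330732519803	0.04138259970813188	0.9618517083314221	824
rs100252	A	G	0.8496705118847746	-0.028450933949458794	0.03450304596409399	0.40960329323012246	824
rs100259	C	T	0.9482446423122286	0.03938920737779408	0.03608540559492937	0.27502871448608235	824
rs100266	G	A	0.5462603176721443	-0.054566306548958124	0.032517070602647274	0.09333111810325588	824
rs100273	T	C	0.24264769787344842	-0.033919666413017566	0.032111410483700836	0.2908257211812507	824
rs100280	A	G	0.07099957616856643	-0.05586768120291705	0.037654627711612494	0.13789197965296573	824
rs100287	C	T	0.3104441885269382	0.004278952634765647	0.041766846362640754	0.9184006530878907	824
rs100294	G	A	0.8498821770735289	0.01865980251919892	0.04109214235509383	0.6497592935163619	824
rs100301	T	C	0.6003630298219944	0.0017018762585294805	0.03457524199739436	0.9607420633516037	824
rs100308	A	G	0.4132083785923916	0.0017295710009776338	0.038445919369787473	0.9641175791934473	824
rs100315	C	T	0.4772225535117986	-0.010071638191543844	0.0383622044381367	0.7929046478718893	824
rs100322	G	A	0.4146809094998096	0.02930662286767506	0.04116616767370736	0.47652026205169407	824
rs100329	T	C	0.5196381748839836	0.01176094394070805	0.035596780332858076	0.7411026714460741	824
rs100336	A	G	0.4410819954767206	0.02523487072844724	0.034587507728402044	0.4656378142685266	824
rs100343	C	T	0.22387341986145548	-0.018398948081705786	0.040936666762024926	0.653107717549804	824
rs100350	G	A	0.8408652223252834	-0.06008528421412162	0.041002346795148234	0.14280885670045726	824
rs100357	T	C	0.7626098466849217	0.05292358801898184	0.039551291336894175	0.18086379890528126	824
rs100364	A	G	0.20873587766190876	-0.0623001870066628	0.03182535762470221	0.050281148474850525	824
rs100371	C	T	0.9157985608568279	0.006458217870438739	0.03723365456220946	0.862296871682891	824
rs100378	G	A	0.8758129720550601	0.08077057977309231	0.03669525290658162	0.027727675014990776	824
rs100385	T	C	0.579869393738896	-0.01371998941725209	0.04031762790600986	0.7336324728511325	824
rs100392	A	G	0.8619050845952507	-0.00801402234012652	0.03523586701114658	0.8200821327507395	824
rs100399	C	T	0.5130805731316351	-0.0030467256078540225	0.038286651294549334	0.9365739220776215	824
rs100406	G	A	0.8074224930913965	0.09912570783348296	0.03566106072096631	0.005441544556322095	824
rs100413	T	C	0.5412219489744173	-0.027257803806258602	0.032607922918880525	0.4031966513048695	824
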
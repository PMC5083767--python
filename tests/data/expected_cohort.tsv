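patient_id	index_date	atc_code	drug	age_years	age_group	period	prescriber
P00000	2011-11-09	N06AA10	nortriptyline	17.37987679671458	teen	2010-2014	specialist
P00001	2010-08-17	N06AB03	fluoxetine	16.566735112936346	teen	2010-2014	GP
P00002	2004-04-29	N06AX11	mirtazapine	14.77344284736482	teen	2004-2009	specialist
P00003	2010-04-13	N06AA09	amitriptyline	11.723477070499658	preteen	2010-2014	specialist
P00004	2013-07-11	N06AB03	fluoxetine	14.38466803559206	teen	2010-2014	specialist
P00005	2010-06-28	N06AX16	venlafaxine	16.87337440109514	teen	2010-2014	specialist
P00006	2010-12-29	N06AB04	citalopram	16.210814510609172	teen	2010-2014	specialist
P00007	2011-01-28	N06AB04	citalopram	17.10335386721424	teen	2010-2014	unknown
P00008	1997-02-24	N06AB04	citalopram	9.453798767967145	child	1994-2003	specialist
P00010	1996-08-05	N06AA02	imipramine	15.2580424366872	teen	1994-2003	specialist
P00011	1998-07-16	N06AA09	amitriptyline	14.507871321013004	teen	1994-2003	GP
P00012	1995-01-09	N06AB05	paroxetine	10.299794661190965	preteen	1994-2003	GP
P00013	2011-02-23	N06AB05	paroxetine	14.510609171800137	teen	2010-2014	specialist
P00014	1999-12-01	N06AB05	paroxetine	15.937029431895962	teen	1994-2003	GP
P00015	1998-04-22	N06AB04	citalopram	16.58590006844627	teen	1994-2003	specialist
P00016	2010-06-23	N06AB06	sertraline	17.60438056125941	teen	2010-2014	specialist
P00017	2010-04-01	N06AB04	citalopram	13.08145106091718	preteen	2010-2014	specialist
P00018	2008-04-09	N06AA09	amitriptyline	7.7180013689253935	child	2004-2009	GP
P00019	2003-06-05	N06AX05	trazodone	15.471594798083505	teen	1994-2003	GP
P00020	2006-12-15	N06AB06	sertraline	11.728952772073923	preteen	2004-2009	specialist
P00021	2003-01-15	N06AA09	amitriptyline	16.906228610540726	teen	1994-2003	GP
P00022	2003-09-16	N06AB05	paroxetine	14.989733059548255	teen	1994-2003	GP
P00023	2010-08-13	N06AB03	fluoxetine	11.813826146475018	preteen	2010-2014	specialist
P00024	2003-12-17	N06AA04	clomipramine	8.895277207392198	child	1994-2003	GP
P00025	2001-03-21	N06AB05	paroxetine	15.45242984257358	teen	1994-2003	GP
P00026	2002-09-24	N06AB05	paroxetine	16.859685147159478	teen	1994-2003	GP
P00027	2010-07-12	N06AB04	citalopram	10.962354551676933	preteen	2010-2014	GP
P00028	2000-06-28	N06AA09	amitriptyline	10.694045174537989	preteen	1994-2003	specialist
P00029	2012-10-25	N06AB03	fluoxetine	16.060232717316907	teen	2010-2014	specialist
P00030	1998-08-21	N06AB05	paroxetine	14.836413415468858	teen	1994-2003	GP
P00031	2009-05-11	N06AB04	citalopram	16.80766598220397	teen	2004-2009	specialist
P00032	2010-03-31	N06AB06	sertraline	15.033538672142368	teen	2010-2014	specialist
P00033	2001-03-06	N06AX11	mirtazapine	8.71731690622861	child	1994-2003	specialist
P00034	1999-06-03	N06AX11	mirtazapine	16.01368925393566	teen	1994-2003	GP
P00035	2000-02-01	N06AA09	amitriptyline	15.811088295687885	teen	1994-2003	specialist
P00036	2010-01-01	N06AB04	citalopram	17.598904859685145	teen	2010-2014	GP
P00037	2010-02-09	N06AA09	amitriptyline	16.588637919233403	teen	2010-2014	specialist
P00038	2008-12-04	N06AB04	citalopram	16.3750855578371	teen	2004-2009	specialist
P00039	2007-09-18	N06AB03	fluoxetine	14.242299794661191	teen	2004-2009	GP
P00040	2010-09-26	N06AA09	amitriptyline	6.203969883641341	child	2010-2014	GP
P00041	1997-01-25	N06AX11	mirtazapine	8.985626283367557	child	1994-2003	GP
P00042	2005-02-25	N06AX16	venlafaxine	15.255304585900069	teen	2004-2009	specialist
P00043	2006-01-12	N06AX05	trazodone	14.220396988364135	teen	2004-2009	GP
P00044	2003-11-29	N06AB05	paroxetine	16.684462696783026	teen	1994-2003	GP
P00046	2012-10-21	N06AB05	paroxetine	16.98836413415469	teen	2010-2014	specialist
P00047	2012-02-10	N06AB03	fluoxetine	14.242299794661191	teen	2010-2014	specialist
P00048	2010-10-23	N06AB06	sertraline	17.57700205338809	teen	2010-2014	specialist
P00049	1999-09-08	N06AA04	clomipramine	15.441478439425051	teen	1994-2003	specialist
P00051	2004-10-28	N06AB06	sertraline	16.993839835728952	teen	2004-2009	specialist
P00052	2010-05-31	N06AB06	sertraline	14.203969883641342	teen	2010-2014	specialist
P00054	2002-02-11	N06AX16	venlafaxine	14.521560574948666	teen	1994-2003	GP
P00055	2002-01-20	N06AA09	amitriptyline	9.158110882956878	child	1994-2003	specialist
P00056	2008-08-31	N06AB03	fluoxetine	7.271731690622861	child	2004-2009	GP
P00057	2011-10-03	N06AB04	citalopram	6.064339493497604	child	2010-2014	specialist
P00058	2011-05-24	N06AX11	mirtazapine	15.233401779603012	teen	2010-2014	specialist
P00059	1995-05-20	N06AB08	fluvoxamine	13.442847364818617	preteen	1994-2003	GP
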